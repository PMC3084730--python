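"""Build a gene-module collection: homolog families plus filtered pathways.

Constructs a toy all-against-all protein alignment table, reduces it to
best gene pairs, links strongly similar genes into homolog modules,
absorbs singletons under the relaxed cutoff, and filters a small pathway
collection for redundancy against them.
"""

import pandas as pd

from smap.modulekit import (Module, build_collection, build_homolog_collection,
                            filter_redundant)

# one best alignment per gene pair (E-value, mutual coverage)
best_pairs = pd.DataFrame(
    [
        ("mybA", "mybB", 1e-120, 0.92),   # strong: same family
        ("mybB", "mybC", 1e-95, 0.88),    # strong: closes the 3-gene family
        ("rad1", "rad2", 1e-80, 0.75),    # strong: 2-gene family
        ("rad2", "radX", 1e-25, 0.65),    # weak: only the relaxed cutoff
        ("lonely", "mybA", 1e-4, 0.9),    # far below every cutoff
    ],
    columns=["gene_a", "gene_b", "e_value", "coverage"],
)

homolog = build_homolog_collection(best_pairs, genes=["orphan"])
print("homolog modules (including singletons):")
for m in homolog:
    print(f"  {m.id:12s} [{m.source}] {sorted(m.genes)}")

pathways = [
    Module("dna_repair", frozenset(["rad1", "rad2", "radX", "polB"]), "GO"),
    Module("proliferation", frozenset(["mybA", "polB", "ccnd", "cdk4"]), "KEGG"),
]
collection = build_collection(homolog, pathways)
print("\nnon-redundant collection:", collection.summary())
for mid, reason, offender in collection.redundancy_log:
    print(f"  excluded {mid}: {reason} with {offender}")

# `dna_repair` is dropped because 3 of its 4 genes sit in one homolog family
# (the evolutionary signal explains it); `proliferation` survives both rules.
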