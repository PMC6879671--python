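"""Wang GO semantic similarity with best-match-average combining.

A term's ancestors contribute S-values decaying by 0.8 per is_a step
(0.6 per part_of); two terms are compared by the ratio of shared to total
contributions, and genes by the best-match average over their annotation
sets.  Scores live in [0, 1]; a pair scoring >= 0.5 counts as functionally
robust.
"""

from coexdriver import GoDag, gene_similarity_bma, s_values, term_similarity

dag = GoDag(
    parents_of={
        "ROOT": {},
        "BINDING": {"ROOT": "is_a"},
        "KINASE": {"BINDING": "is_a"},
        "RECEPTOR": {"BINDING": "is_a"},
    },
    namespace_of={t: "molecular_function" for t in ("ROOT", "BINDING", "KINASE", "RECEPTOR")},
)

print("S-values for KINASE:", {t: round(v, 3) for t, v in sorted(s_values("KINASE", dag).items())})
print(f"sim(BINDING, ROOT)    = {term_similarity('BINDING', 'ROOT', dag):.4f}  (= 9/14)")
print(f"sim(KINASE, RECEPTOR) = {term_similarity('KINASE', 'RECEPTOR', dag):.4f}")

annotations = {"G1": {"KINASE", "BINDING"}, "G2": {"KINASE"}, "G3": {"RECEPTOR"}}
print(f"BMA(G1, G2) = {gene_similarity_bma('G1', 'G2', annotations, dag):.4f}")
print(f"BMA(G1, G1) = {gene_similarity_bma('G1', 'G1', annotations, dag):.4f}  (self = 1)")
print(f"BMA(G2, G3) = {gene_similarity_bma('G2', 'G3', annotations, dag):.4f}")
# Siblings share the BINDING/ROOT ancestry, so they score well below 1 but
# above unrelated namespaces (which would score 0).
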