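"""Project a mouse signature onto a human reference cohort.

Simulates a healthy human expression cohort and a Biomart-style
ortholog map, translates the human matrix into mouse symbol space, and
computes per-sample summed z-scores for two mouse signatures; their
inter-signature Pearson correlation exposes shared co-variation.
"""

from oxsig.orthologs import translate_matrix
from oxsig.scoring import score_signatures
from oxsig.signature import GeneSignature
from oxsig.simulate import (
    mouse_gene_symbols,
    simulate_ortholog_map,
    simulate_reference_cohort,
)
from oxsig.stats import inter_signature_correlation

genes = mouse_gene_symbols(500)
sig_a = GeneSignature("sig_A", frozenset(genes[:40]), frozenset(genes[40:80]))
# sig_B shares half of sig_A's up-genes, so their scores should correlate
sig_b = GeneSignature("sig_B", frozenset(genes[20:60]), frozenset(genes[100:140]))

omap = simulate_ortholog_map(genes, frac_one_to_one=0.9, frac_one_to_many=0.05,
                             frac_missing=0.05, seed=2)
human = simulate_reference_cohort(n_samples=578, n_genes=500, seed=2)
mouse_space, report = translate_matrix(human, omap.inverted())
print(f"translated {report.n_translated} human symbols, "
      f"dropped {report.n_dropped_unmapped} unmapped")

scores = score_signatures(mouse_space, [sig_a, sig_b])
print(f"score matrix: {scores.scores.shape[0]} signatures x "
      f"{scores.scores.shape[1]} samples")
corr = inter_signature_correlation(scores)
r = corr.r.loc['sig_A', 'sig_B']
p = corr.p.loc['sig_A', 'sig_B']
print(f"r(sig_A, sig_B) = {r:.3f} (p = {p:.2e}, n = {corr.n})")
# Positive r: the overlapping up-genes make the two summed z-scores
# rise and fall together across the 578 reference samples.
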