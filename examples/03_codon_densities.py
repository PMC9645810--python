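"""Codon-level ribosome densities and the stop-vs-sense mixed model.

Simulates 3'-end-mapped footprints with a known A-site offset, recovers
per-codon densities, then fits the linear mixed model asking whether stop
codons lose ribosome density relative to sense codons across evolved lines.
"""

import numpy as np

import evoexpr as ev
from evoexpr.simulate import (
    FootprintSimConfig,
    simulate_cds_sequences,
    simulate_codon_fc_table,
    simulate_footprints,
)

seqs = simulate_cds_sequences(40, (100, 250), seed=9)
cfg = FootprintSimConfig(sequences=seqs, frame0_fraction=0.85, reads_per_gene=2000, seed=9)
reads = simulate_footprints(cfg)
lens = {g: len(s) for g, s in seqs.items()}

asite = ev.assign_asite(reads, lens)
periodicity = ev.frame_periodicity(reads, lens)
print(
    f"{asite['n_used']} reads A-site-mapped ({asite['n_outside']} outside the CDS); "
    f"frame fractions {np.round(periodicity['fractions'], 3)} "
    f"(QC {'pass' if periodicity['qc_pass'] else 'FAIL'})"
)

profile = ev.codon_density_profile(asite["counts"], seqs, sample_id="evolved_r1")
print(f"codon densities from {profile.n_qualifying} genes with >= 100 reads")
print(profile.density.dropna().head(4).round(4).to_string())

# stop-vs-sense contrast across 11 lines with a known -0.325 stop effect
table = simulate_codon_fc_table(beta0=0.0, beta1=-0.325, n_lines=11, seed=9)
fit = ev.fit_stop_sense_lmm(table)
print(
    f"\nmixed model: beta0 (sense shift) = {fit.beta0:.3f} (p={fit.beta0_pvalue:.3g}), "
    f"beta1 (stop effect) = {fit.beta1:.3f} (p={fit.beta1_pvalue:.3g})"
)
print("AIC comparison of random-effect structures:")
print(fit.aic_table.to_string(index=False))
print(
    "\nA negative beta1 with the mixed model preferred by AIC indicates stop\n"
    "codons lost ribosome density relative to sense codons consistently across\n"
    "lines -- i.e., faster translation termination in the evolved lines."
)
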