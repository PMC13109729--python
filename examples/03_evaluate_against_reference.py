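"""Score a demultiplexing result against a reference labelling.

Uses the generator truth as the reference (in practice this is often a
SNP-based genotype demultiplexer). Prints per-category concordance, the
micro-averaged precision/recall/F1/MCC pooled over one-vs-rest confusion
totals, and the library-size ratio diagnostics: doublets should carry more
HTO material than the richest singlet donor (ratio > 1), and the poorest
singlet donor more than the negatives (ratio > 1).
"""

from hashdemux import RunConfig, SimConfig, run_demux, simulate
from hashdemux.evaluation import concordance, library_size_ratios, micro_metrics

data, truth = simulate(SimConfig(n_cells=2000, n_hashtags=4, seed=2))
result, _ = run_demux(data, RunConfig(seed=2))

conc = concordance(result.category, truth.category)
print(f"overall concordance: {conc['overall']:.3f}")
for cat, frac in sorted(conc["per_category"].items()):
    print(f"  {cat:10s} {frac:.3f}")

mm = micro_metrics(result.category, truth.category)
print(f"micro P {mm.precision:.3f}  R {mm.recall:.3f}  "
      f"F1 {mm.f1:.3f}  MCC {mm.mcc:.3f}")

ratios = library_size_ratios(result.category, data.hto_library_size)
print(f"HTO doublet/singlet ratio:  {ratios['doublet_singlet_ratio']:.2f}")
print(f"HTO singlet/negative ratio: {ratios['singlet_negative_ratio']:.2f}")
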