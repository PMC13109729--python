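"""Run the demultiplexer across all six data-quality archetypes.

The generator reproduces the recurring failure modes of real hashing data
(weak or over-strong hashtags, ambient contamination, an empty-droplet
cluster, shallow input). Each line prints the archetype, the accuracy
against ground truth, and the final category composition — showing where
the method stays robust and where quality loss bites. The contaminated run
uses the select-k route (k2 = N+1) so the contamination blob is isolated
as its own negative cluster instead of swallowing a hashtag's cluster.
"""

from hashdemux import RunConfig, archetype_suite, run_demux
from hashdemux.evaluation import concordance

for cfg, data, truth in archetype_suite(seed=1, n_cells=3000):
    run_cfg = RunConfig(seed=1)
    if cfg.archetype == "contaminated":
        run_cfg.k2 = cfg.n_hashtags + 1
    result, _ = run_demux(data, run_cfg)
    acc = concordance(result.category, truth.category)["overall"]
    counts = result.counts()
    singlets = sum(v for k, v in counts.items() if k not in ("Doublet", "Negative"))
    print(f"{cfg.archetype:14s} accuracy {acc:.3f}  "
          f"singlets {singlets:4d}  doublets {counts.get('Doublet', 0):3d}  "
          f"negatives {counts.get('Negative', 0):3d}")
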