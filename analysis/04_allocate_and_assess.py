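"""Allocate the demanded composition with the constrained CA (validation run
toward the later observed map, then the future forecast demand) and assess
the validation map with a 1% confusion-matrix sample.
"""

from _shared import get_config
from lucsim import pipeline

cfg = get_config()
art = pipeline.stage_synthetic(cfg)
art.update(pipeline.stage_demand(cfg, art))
art.update(pipeline.stage_suitability(cfg, art))
art.update(pipeline.stage_allocate(cfg, art))
art.update(pipeline.stage_assess(cfg, art))

cm, cm_full = art["confusion"], art["confusion_full"]
print(f"validation vs truth: 1% sample OA={cm.overall_accuracy * 100:.2f}% "
      f"kappa={cm.kappa:.4f} (n={cm.n}); "
      f"full grid OA={cm_full.overall_accuracy * 100:.2f}% kappa={cm_full.kappa:.4f}")
gaps = {c: int((art['future'].grid == c).sum()) - art['targets'][c]
        for c in range(1, 8)}
print("future allocation gaps (allocated - target, cells):", gaps)
print(f"maps -> {cfg.output_dir}/landuse_t1_simulated.asc, landuse_future.asc")
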