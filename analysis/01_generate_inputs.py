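"""Generate the synthetic study area: two-date land-use maps, driving-factor
surfaces, class-area history and paired regional/national indicator series.

The landscape is an 8-class, spatially autocorrelated grid whose composition
drifts between the two dates only along rule-permitted transitions, with
water frozen as the restricted zone.  Artifacts land in results/toy/.
"""

import numpy as np

from _shared import get_config
from lucsim import pipeline

cfg = get_config()
art = pipeline.stage_synthetic(cfg)

t0, t1 = art["t0"], art["t1"]
changed = int((t0.grid != t1.grid).sum())
shares = {t0.legend[c]: f"{(t0.grid == c).mean():.1%}" for c in sorted(t0.legend)
          if (t0.grid == c).any()}
print(f"grid {t0.shape}, cell {t0.cell_area_ha:.0f} ha, "
      f"{changed} cells changed between the two dates "
      f"({changed / t0.grid.size:.1%} of the grid)")
print("baseline composition:", shares)
print(f"restricted (water) cells frozen: {int(art['mask'].sum())}")
print(f"area series: {art['areas']['year'].nunique()} years x "
      f"{art['areas']['class'].nunique()} classes -> {cfg.output_dir}/area_series.csv")
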