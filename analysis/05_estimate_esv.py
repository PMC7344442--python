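"""Estimate the ecosystem-service value of every year's land-use structure
with the regionally revised equivalent-factor model and report the trend.
"""

from _shared import get_config
from lucsim import esv, pipeline

cfg = get_config()
art = pipeline.stage_synthetic(cfg)
art.update(pipeline.stage_esv(cfg, art))

audit = art["audit"]
print("correction factors per year (Q, D, S and their product):")
print(audit.round(3).to_string(index=False))

results = art["esv_results"]
years = sorted(results)
first, last = results[years[0]], results[years[-1]]
print(f"\ntotal revised ESV {years[0]}: {first.total / 1e7:.2f} x10^7 USD; "
      f"{years[-1]}: {last.total / 1e7:.2f} x10^7 USD; "
      f"growth {esv.growth_rate(first.total, last.total):.2f}%")
print("category shares in the final year (%):")
print((last.per_category / last.total * 100).round(2).to_string())
print(f"full trend table -> {cfg.output_dir}/esv_report.csv")
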