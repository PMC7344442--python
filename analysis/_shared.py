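"""Shared plumbing for the numbered analysis scripts."""

from pathlib import Path

from lucsim.config import PipelineConfig, load_config

HERE = Path(__file__).parent


def get_config() -> PipelineConfig:
    cfg = load_config(HERE / "config.yaml")
    if not Path(cfg.output_dir).is_absolute():  # anchor at the repo root
        cfg.output_dir = str(HERE.parent / cfg.output_dir)
    return cfg
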