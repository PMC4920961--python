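"""YAML run configuration: engine thresholds, rule parameters, formulary paths.

Precedence is conventional: shipped defaults < config file < explicit CLI
flags. A config file may carry::

    assume_worst: false
    max_gap_days: 7
    suppression_window_days: 90
    enabled_rules: [DUP-1, DUP-2]       # omit for the full catalog
    rule_parameters:
      PSY-2: {max_daily_mg: 40}
    formulary_csv: path/to/formulary.csv   # replaces the shipped formulary
    antimuscarinic_list: path/to/antimuscarinics.txt
    qt_prolonging_list: path/to/qt.txt
    prioritization_threshold: 5000
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .formulary import Formulary, default_formulary, load_formulary_csv, load_reference_list
from .rules_engine import EngineConfig

__all__ = ["load_run_config", "build_engine_config", "build_formulary"]


def load_run_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if raw is None:
        return {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    return raw


def build_engine_config(raw: dict) -> EngineConfig:
    cfg = EngineConfig()
    if "assume_worst" in raw:
        cfg.assume_worst = bool(raw["assume_worst"])
    if "max_gap_days" in raw:
        cfg.max_gap_days = int(raw["max_gap_days"])
    if "suppression_window_days" in raw:
        cfg.suppression_window_days = int(raw["suppression_window_days"])
    if "enabled_rules" in raw and raw["enabled_rules"] is not None:
        cfg.enabled_rules = list(raw["enabled_rules"])
    if "rule_parameters" in raw and raw["rule_parameters"]:
        cfg.rule_parameters = {k: dict(v) for k, v in raw["rule_parameters"].items()}
    return cfg


def build_formulary(raw: dict, base_dir: Path | None = None) -> Formulary:
    def _resolve(p: str) -> Path:
        path = Path(p)
        if not path.is_absolute() and base_dir is not None:
            path = base_dir / path
        return path

    fm = (
        load_formulary_csv(_resolve(raw["formulary_csv"]))
        if raw.get("formulary_csv")
        else default_formulary()
    )
    if raw.get("antimuscarinic_list"):
        fm = fm.with_reference_tags(
            "antimuscarinic", load_reference_list(_resolve(raw["antimuscarinic_list"]))
        )
    if raw.get("qt_prolonging_list"):
        fm = fm.with_reference_tags(
            "qt_prolonging", load_reference_list(_resolve(raw["qt_prolonging_list"]))
        )
    return fm
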