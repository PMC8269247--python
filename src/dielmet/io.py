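"""Schema-validated table readers/writers and the pipeline configuration."""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = ["SCHEMAS", "read_table", "write_table", "PipelineConfig", "load_config"]

# required columns per table kind
SCHEMAS: dict[str, list[str]] = {
    "samples": ["sample_id", "clock_hour", "period", "replicate", "volume_L", "sample_class"],
    "areas": ["compound", "sample_id", "area"],
    "is_areas": ["internal_standard", "sample_id", "area"],
    "compounds": ["compound", "n_carbon", "n_nitrogen", "quant_mode"],
    "is_spikes": ["internal_standard", "spike_pmol"],
    "additions": ["compound", "level_pmol", "response"],
    "external_standards": [
        "compound", "rf_water", "matrix_unspiked_area", "matrix_spiked_area", "spike_pmol",
    ],
    "covariates": ["t_hours", "clock_hour", "poc_umol", "pn_umol"],
    "transcripts": ["taxon", "ko_id", "sample_id", "abundance"],
    "links": ["metabolite", "ko_id", "role"],
    "concentrations": ["compound", "sample_id", "pmol_per_L"],
    "quotas": ["taxon", "compound", "quota_light_fmol", "quota_dark_fmol"],
    "truth": ["signal_id", "kind", "is_diel", "fold_change", "peak_hour"],
}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a delimited table and validate it against a named schema.

    ``samples`` tables may omit ``clock_hour`` when ``datetime_iso`` is
    present; it is then derived from the timestamp.  Errors name the
    offending column or row.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    if schema == "samples" and "clock_hour" not in df.columns:
        if "datetime_iso" not in df.columns:
            raise ValueError(f"{path}: missing column clock_hour (no datetime_iso to derive it)")
        try:
            ts = pd.to_datetime(df["datetime_iso"], format="ISO8601")
        except (ValueError, TypeError) as err:
            bad = None
            for i, v in enumerate(df["datetime_iso"]):
                try:
                    pd.to_datetime(v)
                except (ValueError, TypeError):
                    bad = i
                    break
            raise ValueError(f"{path}: unparseable datetime at row {bad}") from err
        df["clock_hour"] = ts.dt.hour + ts.dt.minute / 60.0 + ts.dt.second / 3600.0
    if schema == "samples" and "t_hours" not in df.columns:
        if "datetime_iso" not in df.columns:
            raise ValueError(f"{path}: missing column t_hours (no datetime_iso to derive it)")
        ts = pd.to_datetime(df["datetime_iso"], format="ISO8601")
        df["t_hours"] = (ts - ts.min()).dt.total_seconds() / 3600.0
    missing = [c for c in SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column {missing[0]}")
    logger.info("read %s: %d rows x %d cols (%s)", path, len(df), df.shape[1], schema)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    df.to_csv(path, sep=sep, index=False)
    return path


@dataclass
class PipelineConfig:
    """Flat configuration of an end-to-end run.

    File paths are resolved relative to the config file's directory when
    loaded via :func:`load_config`.
    """

    input_dir: str = "."
    out_dir: str = "results"
    # input files (relative to input_dir unless absolute)
    samples: str = "samples.csv"
    areas: str = "areas.csv"
    is_areas: str = "is_areas.csv"
    compounds: str = "compounds.csv"
    is_spikes: str = "is_spikes.csv"
    additions: str = "additions.csv"
    external_standards: str = "external_standards.csv"
    covariates: str = "covariates.csv"
    transcripts: str = "transcripts.csv"
    links: str = ""  # empty -> bundled curated table
    quotas: str = "quotas.csv"
    # analysis parameters
    sampling_interval: float = 4.0
    alpha: float = 0.05
    min_improvement: float = 0.4
    blank_ratio: float = 3.0
    window_start_hour: float | None = None
    harmonics: int = 1
    metric: str = "euclidean_zscore"
    n_permutations: int = 999
    seed: int = 0
    include_all_in_totals: bool = False
    # stoichiometry
    glucose_equiv_per_trehalose: float = 2.0
    atp_per_glucose: float = 30.0
    electrons_per_glucose: float = 24.0
    atp_per_n2: float = 16.0
    electrons_per_n2: float = 8.0
    f_o2_drawdown: float = 0.60

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def path(self, name: str) -> Path:
        rel = getattr(self, name)
        p = Path(rel)
        return p if p.is_absolute() else Path(self.input_dir) / p


def load_config(path: str | Path) -> PipelineConfig:
    """Load a flat-key YAML config; unknown keys are rejected."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    valid = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    # resolve relative dirs against the config file location
    base = path.parent
    for name in ("input_dir", "out_dir"):
        p = Path(getattr(cfg, name))
        if not p.is_absolute():
            setattr(cfg, name, str(base / p))
    return cfg
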