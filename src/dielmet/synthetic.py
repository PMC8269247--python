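"""Synthetic diel-study generator.

Produces complete studies — sample metadata, metabolite and
internal-standard peak areas (with blanks and pooled QC injections),
standard-addition and external-calibration tables, covariates, transcript
series and a ground-truth table — with the statistical structure the
analysis pipeline assumes: triplicate sampling every 4 h over two
multi-day periods, sinusoidal 24-h signals with configurable fold change
and peak hour, multiplicative lognormal replicate noise, a shared
per-sample injection factor carried by all internal standards, and
per-compound matrix ion suppression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .quantify import CompoundInfo

__all__ = [
    "StudyDesign",
    "SignalTruth",
    "MeasurementModel",
    "SyntheticStudy",
    "diel_signal",
    "simulate_study",
    "simulate_null_batch",
    "default_compounds",
    "default_truths",
    "default_transcript_truths",
]

WAVEFORMS = ("cosine", "truncated_cosine")


@dataclass(frozen=True)
class StudyDesign:
    """Sampling plan: two (by default) multi-day periods of 4-hourly casts."""

    start_clock_hour: float = 6.0
    sampling_interval: float = 4.0
    n_days_per_period: tuple[int, ...] = (4, 3)
    gap_between_periods: float = 36.0
    n_replicates: int = 3
    volume_filtered: float = 3.5

    def __post_init__(self) -> None:
        if 24.0 % self.sampling_interval != 0:
            raise ValueError("sampling_interval must divide 24")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.volume_filtered <= 0:
            raise ValueError("volume_filtered must be > 0")
        if not (0 <= self.start_clock_hour < 24):
            raise ValueError("start_clock_hour must be in [0, 24)")

    def time_points(self) -> pd.DataFrame:
        """One row per cast: period, t_hours since study start, clock_hour."""
        rows = []
        t = 0.0
        for p, n_days in enumerate(self.n_days_per_period, start=1):
            n_pts = int(n_days * 24 / self.sampling_interval) + 1
            for i in range(n_pts):
                ti = t + i * self.sampling_interval
                rows.append(
                    {
                        "period": p,
                        "t_hours": ti,
                        "clock_hour": (self.start_clock_hour + ti) % 24.0,
                    }
                )
            t = rows[-1]["t_hours"] + self.gap_between_periods
        return pd.DataFrame(rows)

    @property
    def samples_per_window(self) -> int:
        return int(round(24.0 / self.sampling_interval))


@dataclass(frozen=True)
class SignalTruth:
    """Ground truth of one simulated signal."""

    signal_id: str
    baseline: float
    is_diel: bool = True
    fold_change: float = 2.0
    peak_hour: float = 18.0
    noise_cv: float = 0.2
    waveform: str = "cosine"

    def __post_init__(self) -> None:
        for v in (self.baseline, self.fold_change, self.peak_hour, self.noise_cv):
            if not math.isfinite(v):
                raise ValueError(f"{self.signal_id}: non-finite parameter")
        if self.fold_change < 1:
            raise ValueError(f"{self.signal_id}: fold_change must be >= 1")
        if not self.is_diel and self.fold_change != 1:
            raise ValueError(f"{self.signal_id}: non-diel signal must have fold_change 1")
        if self.noise_cv < 0:
            raise ValueError(f"{self.signal_id}: noise_cv must be >= 0")
        if self.waveform not in WAVEFORMS:
            raise ValueError(f"{self.signal_id}: unknown waveform {self.waveform!r}")


@dataclass(frozen=True)
class MeasurementModel:
    """Instrument/matrix artifact model.

    ``is_injection_cv`` is the CV of a per-sample multiplicative injection
    factor shared by every compound and internal standard in that sample
    (the variance BMIS is meant to remove); ``matrix_suppression`` maps
    compound -> factor in (0, 1]; ``blank_level`` is the fraction of each
    compound's baseline signal that appears in extraction blanks;
    ``qc_cv`` is residual (non-injection) noise of pooled-QC injections.
    """

    is_injection_cv: float = 0.1
    matrix_suppression: float | Mapping[str, float] = 1.0
    blank_level: float = 0.0
    qc_cv: float = 0.02

    def suppression_for(self, compound: str) -> float:
        s = (
            self.matrix_suppression.get(compound, 1.0)
            if isinstance(self.matrix_suppression, Mapping)
            else float(self.matrix_suppression)
        )
        if not 0 < s <= 1:
            raise ValueError(f"matrix suppression for {compound} must be in (0, 1]")
        return s

    def __post_init__(self) -> None:
        if self.is_injection_cv < 0 or self.blank_level < 0 or self.qc_cv < 0:
            raise ValueError("measurement factors must be >= 0")


# ---------------------------------------------------------------------------
# signal model
# ---------------------------------------------------------------------------

def _waveform(theta: np.ndarray, kind: str) -> np.ndarray:
    raw = np.cos(theta)
    if kind == "cosine":
        return raw
    # floor-at-trough cosine, rescaled to attain +1 and -1 exactly
    return 2.0 * np.maximum(raw, 0.0) - 1.0


def diel_signal(t, truth: SignalTruth, design: StudyDesign):
    """Noise-free expected value of a signal at ``t`` hours since start.

    value = baseline * (1 + a * w(2 pi (h - peak_hour)/24)) with
    a = (F - 1)/(F + 1), so the max/min ratio over a cycle equals the fold
    change F exactly (w attains +1 and -1 for both waveforms).
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("non-finite time")
    f = truth.fold_change
    a = (f - 1.0) / (f + 1.0) if truth.is_diel else 0.0
    h = (design.start_clock_hour + t) % 24.0
    theta = 2 * np.pi * (h - truth.peak_hour) / 24.0
    out = truth.baseline * (1.0 + a * _waveform(theta, truth.waveform))
    return out if out.ndim else float(out)


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative lognormal noise with the requested CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# default study content
# ---------------------------------------------------------------------------

# (name, C, N, kegg id, osmolyte, quant_mode, underestimate)
_NAMED_COMPOUNDS = [
    ("trehalose", 12, 0, "C01083", True, "std_addition", False),
    ("sucrose", 12, 0, "C00089", True, "std_addition", False),
    ("DHPS", 3, 0, "C19675", True, "std_addition", False),
    ("glycine betaine", 5, 1, "C00719", True, "isotopologue", False),
    ("homarine", 7, 1, None, True, "matrix_external", False),
    ("DMSP", 5, 0, "C04022", True, "matrix_external", True),
    ("glucosylglycerol", 9, 0, "C06608", True, "matrix_external", False),
    ("isethionic acid", 2, 0, "C05123", True, "matrix_external", False),
    ("proline", 5, 1, "C00148", True, "isotopologue", False),
    ("ectoine", 6, 2, "C06231", True, "matrix_external", False),
    ("glutamic acid", 5, 1, "C00025", True, "isotopologue", False),
    ("guanine", 5, 5, "C00242", False, "isotopologue", False),
    ("glutamine", 5, 2, "C00064", False, "isotopologue", False),
    ("S-adenosyl methionine", 15, 6, "C00019", False, "isotopologue", False),
    ("S-adenosyl homocysteine", 14, 6, "C00021", False, "isotopologue", False),
    ("methionine", 5, 1, "C00073", False, "isotopologue", False),
    ("methylthioadenosine", 11, 5, "C00170", False, "matrix_external", False),
    ("pantothenate", 9, 1, "C00864", False, "matrix_external", False),
    ("riboflavin", 17, 4, "C00255", False, "matrix_external", False),
    ("niacin", 6, 1, "C00253", False, "matrix_external", False),
    ("glutathione", 10, 3, "C00051", False, "isotopologue", False),
    ("AMP", 10, 5, "C00020", False, "matrix_external", False),
    ("arachidonic acid", 20, 0, "C00219", False, "matrix_external", False),
    ("ergosterol", 28, 0, "C01694", False, "matrix_external", False),
]


def default_compounds(n_total: int = 79, seed: int = 0) -> list[CompoundInfo]:
    """Compound panel: curated entries padded with generic analytes."""
    rng = np.random.default_rng(seed)
    out = [
        CompoundInfo(
            name=name,
            n_carbon=c,
            n_nitrogen=n,
            kegg_compound_id=kegg,
            osmolyte=osmo,
            quant_mode=mode,
            isotopologue_partner=f"{name} (13C)" if mode == "isotopologue" else None,
            underestimate_flag=under,
        )
        for name, c, n, kegg, osmo, mode, under in _NAMED_COMPOUNDS[:n_total]
    ]
    for i in range(len(out), n_total):
        out.append(
            CompoundInfo(
                name=f"compound_{i + 1:02d}",
                n_carbon=int(rng.integers(2, 21)),
                n_nitrogen=int(rng.integers(0, 4)),
                quant_mode="matrix_external",
            )
        )
    return out


def default_truths(
    compounds: Sequence[CompoundInfo],
    n_diel: int = 55,
    noise_cv: float = 0.2,
    fold_range: tuple[float, float] = (1.6, 12.8),
    seed: int = 0,
) -> list[SignalTruth]:
    """Signal truths emulating the observed phenomenology.

    The first ``n_diel`` compounds are diel with fold changes drawn
    log-uniformly from ``fold_range`` and peak hours concentrated near
    14:00 and 18:00; the rest are flat.
    """
    rng = np.random.default_rng(seed)
    truths = []
    for i, c in enumerate(compounds):
        baseline = float(np.exp(rng.uniform(np.log(5.0), np.log(5000.0))))
        if i < n_diel:
            f = float(np.exp(rng.uniform(np.log(fold_range[0]), np.log(fold_range[1]))))
            u = rng.random()
            if u < 0.45:
                peak = rng.normal(18.0, 1.0)
            elif u < 0.8:
                peak = rng.normal(14.0, 1.0)
            else:
                peak = rng.uniform(0.0, 24.0)
            truths.append(
                SignalTruth(c.name, baseline, True, f, float(peak % 24.0), noise_cv)
            )
        else:
            truths.append(SignalTruth(c.name, baseline, False, 1.0, 0.0, noise_cv))
    return truths


def default_transcript_truths(
    links: pd.DataFrame,
    metabolite_truths: Sequence[SignalTruth],
    frac_diel: float = 0.6,
    lag_hours: float | None = None,
    lag_sd: float = 4.0,
    noise_cv: float = 0.2,
    seed: int = 0,
) -> list[tuple[str, str, str, SignalTruth]]:
    """Per taxon x KO transcript truths, phase-referenced to metabolites.

    Each link row spawns one series per assigned taxon; diel series peak at
    the metabolite peak plus a lag (fixed ``lag_hours`` or drawn
    N(0, lag_sd)).  Returns (taxon, ko, domain, truth) tuples.
    """
    rng = np.random.default_rng(seed)
    by_name = {t.signal_id: t for t in metabolite_truths}
    prok = ["Chroococcales", "Synechococcales", "Pelagibacterales", "Rhodobacterales"]
    euk = ["Dinophyceae", "Haptophyceae", "Bacillariophyta"]
    out = []
    seen = set()
    for _, row in links.iterrows():
        mt = by_name.get(row["metabolite"])
        if mt is None:
            continue
        taxa = [(t, "prokaryote") for t in rng.choice(prok, size=2, replace=False)]
        taxa.append((str(rng.choice(euk)), "eukaryote"))
        for taxon, domain in taxa:
            key = (taxon, row["ko_id"])
            if key in seen:
                continue
            seen.add(key)
            baseline = float(np.exp(rng.uniform(np.log(10.0), np.log(1000.0))))
            diel = bool(rng.random() < frac_diel) and mt.is_diel
            if diel:
                lag = lag_hours if lag_hours is not None else float(rng.normal(0, lag_sd))
                truth = SignalTruth(
                    f"{taxon}|{row['ko_id']}",
                    baseline,
                    True,
                    float(np.exp(rng.uniform(np.log(2.0), np.log(8.0)))),
                    (mt.peak_hour + lag) % 24.0,
                    noise_cv,
                )
            else:
                truth = SignalTruth(
                    f"{taxon}|{row['ko_id']}", baseline, False, 1.0, 0.0, noise_cv
                )
            out.append((taxon, str(row["ko_id"]), domain, truth))
    return out


# ---------------------------------------------------------------------------
# study simulation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    """Bundle of generated tables (all plain DataFrames)."""

    design: StudyDesign
    samples: pd.DataFrame
    areas: pd.DataFrame
    is_areas: pd.DataFrame
    compounds: pd.DataFrame
    is_spikes: pd.DataFrame
    additions: pd.DataFrame
    external_standards: pd.DataFrame
    covariates: pd.DataFrame
    transcripts: pd.DataFrame
    truth: pd.DataFrame
    quotas: pd.DataFrame

    def compound_info(self) -> list[CompoundInfo]:
        return [
            CompoundInfo(
                name=r["compound"],
                n_carbon=int(r["n_carbon"]),
                n_nitrogen=int(r["n_nitrogen"]),
                kegg_compound_id=r["kegg_compound_id"] if pd.notna(r["kegg_compound_id"]) else None,
                osmolyte=bool(r["osmolyte"]),
                quant_mode=r["quant_mode"],
                isotopologue_partner=r["isotopologue_partner"]
                if pd.notna(r["isotopologue_partner"])
                else None,
                underestimate_flag=bool(r["underestimate_flag"]),
            )
            for _, r in self.compounds.iterrows()
        ]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in (
            "samples", "areas", "is_areas", "compounds", "is_spikes", "additions",
            "external_standards", "covariates", "transcripts", "truth", "quotas",
        ):
            p = out / f"{name}.csv"
            getattr(self, name).to_csv(p, index=False)
            paths[name] = p
        return paths


_DEFAULT_QUOTAS = pd.DataFrame(
    [
        # end-of-light / end-of-dark cell quotas (fmol/cell) and molar mass
        {"taxon": "Crocosphaera", "compound": "trehalose",
         "quota_light_fmol": 0.8, "quota_dark_fmol": 0.07, "molar_mass": 342.3},
        {"taxon": "Prochlorococcus", "compound": "sucrose",
         "quota_light_fmol": 0.0021, "quota_dark_fmol": 0.0014, "molar_mass": 342.3},
    ]
)


def simulate_study(
    design: StudyDesign,
    truths: Sequence[SignalTruth],
    model: MeasurementModel,
    seed: int,
    compounds: Sequence[CompoundInfo] | None = None,
    transcript_truths: Sequence[tuple[str, str, str, SignalTruth]] = (),
    n_qc: int = 6,
    n_blanks: int = 3,
    ref_date: str = "2015-07-26",
) -> SyntheticStudy:
    """Generate one full synthetic study.

    Every source of randomness flows from ``seed``; identical inputs give
    byte-identical tables.  ``truths`` order must match ``compounds`` (a
    generic matrix_external compound is synthesized for any truth without
    one).
    """
    if not truths:
        raise ValueError("need at least one signal truth")
    rng = np.random.default_rng(seed)

    if compounds is None:
        generic = {t.signal_id for t in truths}
        compounds = [
            CompoundInfo(name=t.signal_id, n_carbon=6, quant_mode="matrix_external")
            for t in truths
        ]
    by_name = {c.name: c for c in compounds}
    missing = [t.signal_id for t in truths if t.signal_id not in by_name]
    if missing:
        raise ValueError(f"truths without compound info: {missing[:5]}")

    tp = design.time_points()
    start_dt = datetime.fromisoformat(ref_date) + timedelta(hours=design.start_clock_hour)

    # --- sample metadata -------------------------------------------------
    rows = []
    for _, cast in tp.iterrows():
        for rep in range(1, design.n_replicates + 1):
            rows.append(
                {
                    "sample_id": f"S{int(cast['period'])}_{int(cast['t_hours']):03d}_r{rep}",
                    "datetime_iso": (start_dt + timedelta(hours=cast["t_hours"])).isoformat(),
                    "clock_hour": cast["clock_hour"],
                    "period": int(cast["period"]),
                    "replicate": rep,
                    "volume_L": design.volume_filtered,
                    "sample_class": "field",
                    "t_hours": cast["t_hours"],
                }
            )
    for i in range(1, n_blanks + 1):
        rows.append(
            {
                "sample_id": f"BLK_{i}",
                "datetime_iso": start_dt.isoformat(),
                "clock_hour": design.start_clock_hour,
                "period": 0,
                "replicate": i,
                "volume_L": design.volume_filtered,
                "sample_class": "blank",
                "t_hours": 0.0,
            }
        )
    for i in range(1, n_qc + 1):
        rows.append(
            {
                "sample_id": f"QC_{i}",
                "datetime_iso": start_dt.isoformat(),
                "clock_hour": design.start_clock_hour,
                "period": 0,
                "replicate": i,
                "volume_L": design.volume_filtered,
                "sample_class": "qc",
                "t_hours": 0.0,
            }
        )
    samples = pd.DataFrame(rows)
    all_ids = samples["sample_id"].to_numpy()
    n_samples = len(samples)
    injection = _lognormal_factors(rng, model.is_injection_cv, n_samples)
    inj = pd.Series(injection, index=all_ids)

    # --- response factors and suppression --------------------------------
    names = [t.signal_id for t in truths]
    rf = pd.Series(
        np.exp(rng.uniform(np.log(200.0), np.log(5000.0), size=len(names))), index=names
    )
    supp = pd.Series({n: model.suppression_for(n) for n in names})

    # --- field areas ------------------------------------------------------
    field = samples[samples["sample_class"] == "field"]
    t_field = field["t_hours"].to_numpy()
    area_rows = []
    mean_amount = {}
    for truth in truths:
        expected = diel_signal(t_field, truth, design)  # pmol/L
        noise = _lognormal_factors(rng, truth.noise_cv, len(t_field))
        amount = expected * design.volume_filtered  # pmol on filter
        mean_amount[truth.signal_id] = float(np.mean(amount))
        areas_c = amount * noise * rf[truth.signal_id] * supp[truth.signal_id]
        areas_c = areas_c * inj[field["sample_id"]].to_numpy()
        for sid, a in zip(field["sample_id"], areas_c):
            area_rows.append({"compound": truth.signal_id, "sample_id": sid, "area": a})

    # --- QC and blank areas ----------------------------------------------
    qc_ids = samples.loc[samples["sample_class"] == "qc", "sample_id"]
    blank_ids = samples.loc[samples["sample_class"] == "blank", "sample_id"]
    for truth in truths:
        base = mean_amount[truth.signal_id] * rf[truth.signal_id] * supp[truth.signal_id]
        qc_noise = _lognormal_factors(rng, model.qc_cv, len(qc_ids))
        for sid, nz in zip(qc_ids, qc_noise):
            area_rows.append(
                {"compound": truth.signal_id, "sample_id": sid, "area": base * nz * inj[sid]}
            )
        for sid in blank_ids:
            area_rows.append(
                {
                    "compound": truth.signal_id,
                    "sample_id": sid,
                    "area": model.blank_level * base * inj[sid],
                }
            )
    areas = pd.DataFrame(area_rows)

    # --- internal standards ----------------------------------------------
    is_rows = []
    spike_rows = []
    # two generic injection standards + one heavy partner per isotopologue compound
    for k, is_name in enumerate(["d3-alanine (IS)", "13C-caffeine (IS)"]):
        base_area = 1.0e6 * (k + 1)
        spike_rows.append({"internal_standard": is_name, "spike_pmol": 100.0})
        for sid in all_ids:
            is_rows.append(
                {"internal_standard": is_name, "sample_id": sid, "area": base_area * inj[sid]}
            )
    for truth in truths:
        info = by_name[truth.signal_id]
        if info.quant_mode != "isotopologue":
            continue
        partner = info.isotopologue_partner
        spike = 100.0
        spike_rows.append({"internal_standard": partner, "spike_pmol": spike})
        # co-eluting heavy analogue: same rf and suppression as the light form
        base_area = spike * rf[truth.signal_id] * supp[truth.signal_id]
        for sid in all_ids:
            is_rows.append(
                {"internal_standard": partner, "sample_id": sid, "area": base_area * inj[sid]}
            )
    is_areas = pd.DataFrame(is_rows)
    is_spikes = pd.DataFrame(spike_rows)

    # --- standard additions & external standards -------------------------
    add_rows = []
    ext_rows = []
    for truth in truths:
        info = by_name[truth.signal_id]
        endo = mean_amount[truth.signal_id]  # pmol in pooled aliquot
        if info.quant_mode == "std_addition":
            level = max(endo, 1.0)
            for lv in (0.0, level, 2.0 * level, 3.0 * level):
                add_rows.append(
                    {
                        "compound": truth.signal_id,
                        "level_pmol": lv,
                        "response": (endo + lv) * rf[truth.signal_id] * supp[truth.signal_id],
                    }
                )
        elif info.quant_mode == "matrix_external":
            spike = max(endo, 1.0)
            ext_rows.append(
                {
                    "compound": truth.signal_id,
                    "rf_water": rf[truth.signal_id],
                    "matrix_unspiked_area": endo * rf[truth.signal_id] * supp[truth.signal_id],
                    "matrix_spiked_area": (endo + spike)
                    * rf[truth.signal_id]
                    * supp[truth.signal_id],
                    "spike_pmol": spike,
                }
            )
    additions = pd.DataFrame(add_rows, columns=["compound", "level_pmol", "response"])
    external_standards = pd.DataFrame(
        ext_rows,
        columns=["compound", "rf_water", "matrix_unspiked_area", "matrix_spiked_area", "spike_pmol"],
    )

    # --- covariates -------------------------------------------------------
    poc_truth = SignalTruth("POC", 3.52, True, 1.2, 18.0, 0.0)
    pn_truth = SignalTruth("PN", 0.44, True, 1.15, 18.0, 0.0)
    cov = tp.copy()
    cov["poc_umol"] = diel_signal(cov["t_hours"].to_numpy(), poc_truth, design) * \
        _lognormal_factors(rng, 0.02, len(cov))
    cov["pn_umol"] = diel_signal(cov["t_hours"].to_numpy(), pn_truth, design) * \
        _lognormal_factors(rng, 0.02, len(cov))
    cov["Crocosphaera_cells_per_L"] = 0.16e6 * _lognormal_factors(rng, 0.05, len(cov))
    cov["Prochlorococcus_cells_per_L"] = 161.0e6 * _lognormal_factors(rng, 0.05, len(cov))
    cov["Crocosphaera_ugC_per_L"] = cov["Crocosphaera_cells_per_L"] * 1.0e-6  # ~1 pg C/cell
    cov["Prochlorococcus_ugC_per_L"] = cov["Prochlorococcus_cells_per_L"] * 60.0e-9

    # --- transcripts ------------------------------------------------------
    rep1 = field[field["replicate"] == 1]
    tr_rows = []
    for taxon, ko, domain, truth in transcript_truths:
        expected = diel_signal(rep1["t_hours"].to_numpy(), truth, design)
        noise = _lognormal_factors(rng, truth.noise_cv, len(rep1))
        for sid, v in zip(rep1["sample_id"], expected * noise):
            tr_rows.append(
                {"taxon": taxon, "ko_id": ko, "domain": domain, "sample_id": sid, "abundance": v}
            )
    transcripts = pd.DataFrame(
        tr_rows, columns=["taxon", "ko_id", "domain", "sample_id", "abundance"]
    )

    # --- truth table ------------------------------------------------------
    truth_rows = [
        {
            "signal_id": t.signal_id,
            "kind": "metabolite",
            "baseline": t.baseline,
            "is_diel": t.is_diel,
            "fold_change": t.fold_change,
            "peak_hour": t.peak_hour,
            "noise_cv": t.noise_cv,
            "waveform": t.waveform,
        }
        for t in truths
    ] + [
        {
            "signal_id": t.signal_id,
            "kind": "transcript",
            "baseline": t.baseline,
            "is_diel": t.is_diel,
            "fold_change": t.fold_change,
            "peak_hour": t.peak_hour,
            "noise_cv": t.noise_cv,
            "waveform": t.waveform,
        }
        for _, _, _, t in transcript_truths
    ]

    compounds_df = pd.DataFrame(
        [
            {
                "compound": c.name,
                "n_carbon": c.n_carbon,
                "n_nitrogen": c.n_nitrogen,
                "kegg_compound_id": c.kegg_compound_id,
                "osmolyte": c.osmolyte,
                "quant_mode": c.quant_mode,
                "isotopologue_partner": c.isotopologue_partner,
                "underestimate_flag": c.underestimate_flag,
            }
            for c in compounds
            if c.name in by_name
        ]
    )

    return SyntheticStudy(
        design=design,
        samples=samples,
        areas=areas,
        is_areas=is_areas,
        compounds=compounds_df,
        is_spikes=is_spikes,
        additions=additions,
        external_standards=external_standards,
        covariates=cov,
        transcripts=transcripts,
        truth=pd.DataFrame(truth_rows),
        quotas=_DEFAULT_QUOTAS.copy(),
    )


def simulate_null_batch(
    design: StudyDesign,
    n_signals: int,
    noise_cv: float,
    seed: int,
) -> SyntheticStudy:
    """Study in which every signal is non-diel (fold change 1).

    Measurement artifacts are disabled so areas are proportional to
    concentrations; intended for type-I-error calibration of the rhythm
    test.
    """
    if n_signals < 1:
        raise ValueError("n_signals must be >= 1")
    truths = [
        SignalTruth(f"null_{i + 1:04d}", 100.0, False, 1.0, 0.0, noise_cv)
        for i in range(n_signals)
    ]
    model = MeasurementModel(is_injection_cv=0.0, matrix_suppression=1.0, qc_cv=0.0)
    return simulate_study(design, truths, model, seed=seed)
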