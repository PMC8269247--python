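"""Conversion of raw LC-MS peak areas to pmol/L concentrations.

Three quantification modes are supported, chosen per compound:

* ``isotopologue`` — ratio to a co-eluting heavy-labelled internal standard
  spiked at known amount (injection and suppression cancel in the ratio).
* ``std_addition`` — ordinary least squares of response on spiked amount;
  the endogenous amount is the |x-intercept| and the slope doubles as a
  matrix response factor for the remaining samples.
* ``matrix_external`` — external calibration with response factors measured
  both in water and in pooled matrix; the matrix factor corrects for ion
  suppression.

Areas destined for the external modes are first normalized with
best-matched internal standard (BMIS) selection: for every compound the
labelled standard that most reduces the relative standard deviation across
pooled-QC injections is applied, but only when the improvement over no
normalization exceeds a configurable threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CompoundInfo",
    "QuantificationError",
    "bmis_select",
    "quant_isotopologue",
    "quant_standard_addition",
    "quant_matrix_external",
    "blank_flag",
    "quantify_study",
]

QUANT_MODES = ("isotopologue", "std_addition", "matrix_external")


class QuantificationError(ValueError):
    """Raised when a quantification mode cannot be applied."""


@dataclass
class CompoundInfo:
    """Identity, stoichiometry and quantification metadata of one analyte."""

    name: str
    n_carbon: int
    n_nitrogen: int = 0
    kegg_compound_id: str | None = None
    osmolyte: bool = False
    quant_mode: str = "matrix_external"
    isotopologue_partner: str | None = None
    underestimate_flag: bool = False

    def __post_init__(self) -> None:
        if self.n_carbon < 1:
            raise ValueError(f"{self.name}: n_carbon must be >= 1")
        if self.n_nitrogen < 0:
            raise ValueError(f"{self.name}: n_nitrogen must be >= 0")
        if self.quant_mode not in QUANT_MODES:
            raise ValueError(f"{self.name}: unknown quant_mode {self.quant_mode!r}")
        if self.quant_mode == "isotopologue" and not self.isotopologue_partner:
            raise ValueError(f"{self.name}: isotopologue mode requires a partner IS")


# ---------------------------------------------------------------------------
# BMIS
# ---------------------------------------------------------------------------

def _rsd(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    m = x.mean()
    if m == 0:
        return math.inf
    return float(x.std(ddof=1) / abs(m))


def bmis_select(
    areas: pd.DataFrame,
    is_areas: pd.DataFrame,
    qc_sample_ids: Sequence[str],
    min_improvement: float = 0.4,
) -> tuple[pd.Series, pd.DataFrame, pd.DataFrame]:
    """Choose the best-matched internal standard per compound.

    Parameters
    ----------
    areas
        Wide matrix of raw areas, compounds x samples.
    is_areas
        Wide matrix of internal-standard areas, standards x samples.
    qc_sample_ids
        Pooled-QC sample ids (>= 2) used to score candidates.
    min_improvement
        Minimum fractional RSD improvement over "none" for an IS to be
        accepted (default 0.4).

    Returns
    -------
    (chosen, normalized, report)
        ``chosen`` maps compound -> IS name or ``"none"``; ``normalized``
        is the matrix with the per-compound chosen normalization applied
        (``raw * mean QC IS area / per-sample IS area``); ``report`` holds
        RSD before/after per compound.
    """
    qc = [s for s in qc_sample_ids]
    if len(qc) < 2:
        raise ValueError("need >= 2 pooled-QC samples for BMIS")
    missing = [s for s in qc if s not in areas.columns]
    if missing:
        raise ValueError(f"QC samples missing from area matrix: {missing}")

    candidates: dict[str, pd.Series] = {}
    for is_name, row in is_areas.iterrows():
        qc_vals = row[qc].astype(float)
        if qc_vals.isna().any() or (qc_vals <= 0).any():
            logger.warning("BMIS: excluding IS %s (missing/invalid QC areas)", is_name)
            continue
        # per-sample normalization factor: mean IS area over QC / IS area
        candidates[str(is_name)] = qc_vals.mean() / row.astype(float)

    chosen = {}
    report_rows = []
    normalized = areas.astype(float).copy()
    for compound, raw in areas.iterrows():
        raw = raw.astype(float)
        rsd_none = _rsd(raw[qc].to_numpy())
        best_name, best_rsd = "none", rsd_none
        for is_name, factor in candidates.items():
            rsd_c = _rsd((raw[qc] * factor[qc]).to_numpy())
            if rsd_c < best_rsd:
                best_name, best_rsd = is_name, rsd_c
        improvement = 0.0 if rsd_none == 0 else (rsd_none - best_rsd) / rsd_none
        if best_name != "none" and rsd_none > 0 and improvement >= min_improvement:
            chosen[compound] = best_name
            normalized.loc[compound] = raw * candidates[best_name]
        else:
            chosen[compound] = "none"
            best_rsd = rsd_none
        report_rows.append(
            {
                "compound": compound,
                "is_chosen": chosen[compound],
                "rsd_before": rsd_none,
                "rsd_after": best_rsd,
            }
        )
    return pd.Series(chosen, name="is_chosen"), normalized, pd.DataFrame(report_rows)


# ---------------------------------------------------------------------------
# quantification modes
# ---------------------------------------------------------------------------

def quant_isotopologue(
    area_light: float, area_heavy: float, spike_amount: float, volume: float
) -> float:
    """pmol/L from the light/heavy area ratio of an isotopologue pair."""
    if volume <= 0:
        raise QuantificationError("volume must be > 0")
    if area_heavy <= 0:
        raise QuantificationError("heavy isotopologue area must be > 0")
    return float(area_light) / float(area_heavy) * float(spike_amount) / float(volume)


def quant_standard_addition(
    added_levels: Sequence[float],
    responses: Sequence[float],
    volume: float,
) -> tuple[float, float, float, bool]:
    """Standard-addition quantification by x-intercept extrapolation.

    Returns ``(conc_pmol_per_L, se, slope, clipped)`` where ``slope`` is the
    fitted response factor (area per pmol, usable as a matrix response
    factor) and ``clipped`` marks a negative endogenous estimate clipped to
    zero.  SE is propagated from the regression coefficient covariance.
    """
    x = np.asarray(added_levels, dtype=float)
    y = np.asarray(responses, dtype=float)
    if volume <= 0:
        raise QuantificationError("volume must be > 0")
    if len(x) < 3 or 0.0 not in x:
        raise QuantificationError("need >= 3 addition levels including 0")
    design = np.column_stack([x, np.ones_like(x)])
    coef, res, _, _ = np.linalg.lstsq(design, y, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    flat_tol = 1e-9 * max(1.0, float(np.max(np.abs(y)))) / float(x.max() - x.min())
    if slope <= flat_tol:
        raise QuantificationError("non-positive standard-addition slope")
    endo = intercept / slope  # pmol
    # OLS coefficient covariance, then delta method on intercept/slope
    dof = len(x) - 2
    ssr = float(np.sum((y - design @ coef) ** 2))
    cov = (ssr / dof if dof > 0 else 0.0) * np.linalg.inv(design.T @ design)
    grad = np.array([-intercept / slope**2, 1.0 / slope])
    var = float(grad @ cov @ grad)
    se_amount = math.sqrt(var) if var > 0 else 0.0
    clipped = endo < 0
    conc = max(endo, 0.0) / volume
    return conc, se_amount / volume, slope, clipped


def quant_matrix_external(
    area: float,
    rf_water: float,
    rf_matrix: float,
    volume: float,
) -> tuple[float, float]:
    """pmol/L from matrix-matched external calibration.

    ``rf_matrix`` is the response factor measured in pooled matrix
    ((spiked - unspiked)/spike amount); the returned suppression factor is
    ``rf_matrix / rf_water``.
    """
    if volume <= 0:
        raise QuantificationError("volume must be > 0")
    if rf_matrix <= 0:
        raise QuantificationError("non-positive matrix response factor")
    return float(area) / rf_matrix / volume, rf_matrix / rf_water


# ---------------------------------------------------------------------------
# blanks
# ---------------------------------------------------------------------------

def blank_flag(
    field_areas: pd.DataFrame,
    blank_areas: pd.DataFrame | None,
    ratio_threshold: float = 3.0,
) -> pd.DataFrame:
    """Flag compounds whose signal is not well above extraction blanks.

    A compound fails when its mean field area is below ``ratio_threshold``
    times its mean blank area.  Flags annotate, never delete.
    """
    rows = []
    for compound, raw in field_areas.iterrows():
        if blank_areas is None or blank_areas.shape[1] == 0 or compound not in blank_areas.index:
            rows.append({"compound": compound, "blank_flag": "not_evaluated",
                         "mean_field": float(raw.mean()), "mean_blank": math.nan})
            continue
        mean_blank = float(blank_areas.loc[compound].astype(float).mean())
        mean_field = float(raw.astype(float).mean())
        ok = mean_blank == 0 or mean_field >= ratio_threshold * mean_blank
        rows.append({"compound": compound, "blank_flag": "pass" if ok else "fail",
                     "mean_field": mean_field, "mean_blank": mean_blank})
    return pd.DataFrame(rows).set_index("compound")


# ---------------------------------------------------------------------------
# study-level driver
# ---------------------------------------------------------------------------

def quantify_study(
    areas: pd.DataFrame,
    is_areas: pd.DataFrame,
    samples: pd.DataFrame,
    compounds: Sequence[CompoundInfo],
    is_spikes: Mapping[str, float],
    additions: pd.DataFrame | None = None,
    external_standards: pd.DataFrame | None = None,
    min_improvement: float = 0.4,
    blank_ratio: float = 3.0,
) -> pd.DataFrame:
    """Quantify every compound in every field sample.

    Parameters
    ----------
    areas, is_areas
        Long tables with columns (``compound``/``internal_standard``,
        ``sample_id``, ``area``).
    samples
        Sample metadata with ``sample_id``, ``sample_class`` (field / qc /
        blank) and ``volume_L``.
    compounds
        CompoundInfo records; drives the per-compound mode.
    is_spikes
        Spike amount (pmol) per internal standard.
    additions
        Standard-addition table (``compound``, ``level_pmol``,
        ``response``) for ``std_addition`` compounds.
    external_standards
        Table (``compound``, ``rf_water``, ``matrix_unspiked_area``,
        ``matrix_spiked_area``, ``spike_pmol``) for ``matrix_external``
        compounds.

    Returns
    -------
    Long DataFrame: compound, sample_id, pmol_per_L, se, method, is_used,
    flags (``;``-separated annotations, empty when clean).
    """
    wide = areas.pivot(index="compound", columns="sample_id", values="area")
    is_wide = is_areas.pivot(index="internal_standard", columns="sample_id", values="area")
    meta = samples.set_index("sample_id")
    field_ids = [s for s in wide.columns if meta.loc[s, "sample_class"] == "field"]
    qc_ids = [s for s in wide.columns if meta.loc[s, "sample_class"] == "qc"]
    blank_ids = [s for s in wide.columns if meta.loc[s, "sample_class"] == "blank"]

    chosen, normalized, _ = bmis_select(wide, is_wide, qc_ids, min_improvement)
    blanks = wide[blank_ids] if blank_ids else None
    bflags = blank_flag(wide[field_ids], blanks, blank_ratio)

    add_fits: dict[str, tuple[float, float]] = {}
    if additions is not None:
        for name, grp in additions.groupby("compound"):
            _, se, slope, _ = quant_standard_addition(
                grp["level_pmol"].to_numpy(), grp["response"].to_numpy(), 1.0
            )
            add_fits[name] = (slope, se)

    ext = (
        external_standards.set_index("compound")
        if external_standards is not None
        else None
    )

    out = []
    for info in compounds:
        if info.name not in wide.index:
            logger.warning("quantify: compound %s absent from area matrix", info.name)
            continue
        flags = []
        if info.underestimate_flag:
            flags.append("underestimate")
        bf = bflags.loc[info.name, "blank_flag"] if info.name in bflags.index else "not_evaluated"
        if bf == "fail":
            flags.append("blank")
        for s in field_ids:
            vol = float(meta.loc[s, "volume_L"])
            row_flags = list(flags)
            se = math.nan
            is_used = "none"
            try:
                if info.quant_mode == "isotopologue":
                    partner = info.isotopologue_partner
                    conc = quant_isotopologue(
                        float(wide.loc[info.name, s]),
                        float(is_wide.loc[partner, s]),
                        float(is_spikes[partner]),
                        vol,
                    )
                    is_used = partner
                elif info.quant_mode == "std_addition":
                    if info.name not in add_fits:
                        raise QuantificationError(
                            f"no standard-addition curve for {info.name}"
                        )
                    slope, _ = add_fits[info.name]
                    amount = float(normalized.loc[info.name, s]) / slope
                    conc = amount / vol
                    is_used = chosen[info.name]
                else:  # matrix_external
                    if ext is None or info.name not in ext.index:
                        raise QuantificationError(
                            f"no external standards for {info.name}"
                        )
                    e = ext.loc[info.name]
                    rf_matrix = (
                        float(e["matrix_spiked_area"]) - float(e["matrix_unspiked_area"])
                    ) / float(e["spike_pmol"])
                    conc, _ = quant_matrix_external(
                        float(normalized.loc[info.name, s]),
                        float(e["rf_water"]),
                        rf_matrix,
                        vol,
                    )
                    is_used = chosen[info.name]
            except QuantificationError as err:
                logger.warning("quantify: %s / %s failed: %s", info.name, s, err)
                conc = math.nan
                row_flags.append("failed")
            out.append(
                {
                    "compound": info.name,
                    "sample_id": s,
                    "pmol_per_L": conc,
                    "se": se,
                    "method": info.quant_mode,
                    "is_used": is_used,
                    "flags": ";".join(row_flags),
                }
            )
    return pd.DataFrame(out)
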