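"""Metabolite <-> transcript linkage via curated KEGG-ortholog tables.

Transcripts are aggregated to taxon x KO series, joined to metabolites
through an offline curated link table (metabolite, KEGG compound id, KO,
role), and — for pairs where both layers are significantly diel — the
circular lag between peak hours is analyzed.  Prokaryotic and eukaryotic
layers are processed identically but never merged.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "default_links",
    "aggregate_transcripts",
    "link_and_classify",
    "circular_lag",
    "peak_time_association",
]

# curated offline link fixture: (metabolite, kegg compound id, KO, role)
_DEFAULT_LINKS = [
    ("trehalose", "C01083", "K00697", "produces"),   # T6P synthase
    ("trehalose", "C01083", "K01087", "produces"),   # T6P phosphatase
    ("trehalose", "C01083", "K01194", "consumes"),   # trehalase
    ("sucrose", "C00089", "K00696", "produces"),     # sucrose-P synthase
    ("sucrose", "C00089", "K01193", "consumes"),     # invertase
    ("DHPS", "C19675", "K15509", "consumes"),        # hpsN-like
    ("glycine betaine", "C00719", "K00130", "produces"),
    ("glycine betaine", "C00719", "K00544", "consumes"),
    ("DMSP", "C04022", "K17486", "consumes"),        # demethylase
    ("glutamic acid", "C00025", "K01915", "consumes"),
    ("glutamine", "C00064", "K01915", "produces"),   # glutamine synthetase
    ("glutamine", "C00064", "K00265", "consumes"),
    ("S-adenosyl methionine", "C00019", "K00789", "produces"),
    ("S-adenosyl methionine", "C00019", "K00558", "consumes"),
    ("S-adenosyl homocysteine", "C00021", "K00558", "produces"),
    ("S-adenosyl homocysteine", "C00021", "K01251", "consumes"),
    ("methionine", "C00073", "K00549", "produces"),
    ("methionine", "C00073", "K00789", "consumes"),
    ("AMP", "C00020", "K00939", "both"),
    ("pantothenate", "C00864", "K01918", "produces"),
    ("riboflavin", "C00255", "K00793", "produces"),
    ("niacin", "C00253", "K00763", "consumes"),
    ("glutathione", "C00051", "K21456", "produces"),
    ("guanine", "C00242", "K00527", "consumes"),
    ("glucosylglycerol", "C06608", "K05946", "produces"),
]


def default_links() -> pd.DataFrame:
    """Bundled curated metabolite <-> KO link table."""
    df = pd.DataFrame(
        _DEFAULT_LINKS, columns=["metabolite", "kegg_compound_id", "ko_id", "role"]
    )
    return df


def aggregate_transcripts(contigs: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Sum contig abundances sharing the same taxon and KO.

    Rows lacking a KO assignment are dropped and counted.  Returns the
    aggregated long table (taxon, ko_id, [domain,] sample_id, abundance)
    and the number of dropped rows.
    """
    required = {"taxon", "ko_id", "sample_id", "abundance"}
    missing = required - set(contigs.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    has_ko = contigs["ko_id"].notna() & (contigs["ko_id"].astype(str) != "")
    n_dropped = int((~has_ko).sum())
    if n_dropped:
        logger.warning("aggregate_transcripts: dropped %d rows without KO", n_dropped)
    keep = contigs[has_ko]
    keys = ["taxon", "ko_id", "sample_id"]
    if "domain" in keep.columns:
        keys = ["taxon", "ko_id", "domain", "sample_id"]
    dups = keep.duplicated(subset=keys).sum()
    if dups:
        logger.warning("aggregate_transcripts: summing %d duplicate rows", dups)
    agg = keep.groupby(keys, as_index=False)["abundance"].sum()
    return agg, n_dropped


def link_and_classify(
    links: pd.DataFrame,
    transcript_results: pd.DataFrame,
    metabolite_results: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Join metabolite and transcript rhythm results through the link table.

    Parameters
    ----------
    links
        Columns ``metabolite``, ``ko_id``, ``role`` (plus optional ids).
    transcript_results
        Rhythm results per taxon x KO with columns ``taxon``, ``ko_id``,
        ``is_diel``, ``peak_hour`` (plus optional ``domain``).
    metabolite_results
        Rhythm results per metabolite: ``signal_id``, ``is_diel``,
        ``peak_hour``.

    Returns
    -------
    (joined, per_metabolite, unlinked)
        ``joined`` holds one row per (metabolite, taxon, KO, role) with
        diel flags and peak hours of both sides and the circular lag where
        both peaks are defined; ``per_metabolite`` counts linked and diel
        transcripts; ``unlinked`` lists metabolites with no joined row.
    """
    met = metabolite_results.rename(
        columns={"signal_id": "metabolite", "is_diel": "metabolite_is_diel",
                 "peak_hour": "metabolite_peak_hour"}
    )[["metabolite", "metabolite_is_diel", "metabolite_peak_hour"]]
    known = set(met["metabolite"])
    bad = sorted(set(links["metabolite"]) - known)
    if bad:
        logger.warning("link_and_classify: skipping links to unknown metabolites %s", bad)
    use_links = links[links["metabolite"].isin(known)]

    tr_cols = ["taxon", "ko_id", "is_diel", "peak_hour"]
    if "domain" in transcript_results.columns:
        tr_cols.append("domain")
    tr = transcript_results[tr_cols].rename(
        columns={"is_diel": "transcript_is_diel", "peak_hour": "transcript_peak_hour"}
    )

    joined = use_links.merge(tr, on="ko_id", how="inner").merge(met, on="metabolite")
    if not joined.empty:
        lags = np.full(len(joined), np.nan)
        both = (
            joined["metabolite_peak_hour"].notna()
            & joined["transcript_peak_hour"].notna()
        ).to_numpy()
        lags[both] = circular_lag(
            joined.loc[both, "metabolite_peak_hour"].to_numpy(),
            joined.loc[both, "transcript_peak_hour"].to_numpy(),
        )
        joined = joined.assign(lag_hours=lags)

    per_rows = []
    for m in met["metabolite"]:
        sub = joined[joined["metabolite"] == m] if not joined.empty else joined
        per_rows.append(
            {
                "metabolite": m,
                "n_transcripts": len(sub),
                "n_diel_transcripts": int(sub["transcript_is_diel"].sum()) if len(sub) else 0,
                "n_taxa": sub["taxon"].nunique() if len(sub) else 0,
            }
        )
    per_metabolite = pd.DataFrame(per_rows)
    unlinked = per_metabolite.loc[per_metabolite["n_transcripts"] == 0, "metabolite"].tolist()
    return joined, per_metabolite, unlinked


def circular_lag(peak_a, peak_b):
    """Signed circular lag peak_b - peak_a in hours, wrapped into (-12, 12]."""
    a = np.asarray(peak_a, dtype=float)
    b = np.asarray(peak_b, dtype=float)
    if np.any(~np.isfinite(a)) or np.any(~np.isfinite(b)):
        raise ValueError("undefined peak hour")
    lag = (b - a + 12.0) % 24.0 - 12.0
    lag = np.where(lag == -12.0, 12.0, lag)
    return lag if lag.ndim else float(lag)


def _circ_corr(alpha: np.ndarray, beta: np.ndarray) -> tuple[float, float]:
    """Circular-circular correlation (sine of centered angles) with asymptotic p."""
    sa = np.sin(alpha - stats.circmean(alpha))
    sb = np.sin(beta - stats.circmean(beta))
    denom = math.sqrt(float(np.sum(sa**2) * np.sum(sb**2)))
    if denom == 0:
        return math.nan, math.nan
    r = float(np.sum(sa * sb)) / denom
    n = len(alpha)
    l20 = np.mean(sa**2)
    l02 = np.mean(sb**2)
    l22 = np.mean(sa**2 * sb**2)
    if l22 == 0:
        return r, math.nan
    z = math.sqrt(n * l20 * l02 / l22) * r
    return r, float(2 * stats.norm.sf(abs(z)))


def peak_time_association(
    metabolite_peaks: Sequence[float],
    transcript_peaks: Sequence[float],
    bin_width: float = 2.0,
) -> dict:
    """Association between paired metabolite and transcript peak hours.

    Pearson correlation is computed on the peak clock hours as plain
    numbers in [0, 24) (treating them as the printed quantities, which is
    statistically dubious for circular data); a circular-circular
    correlation is reported alongside as a robustness check, plus a lag
    histogram at ``bin_width``-hour bins over (-12, 12].

    Raises ``ValueError`` with < 3 pairs.
    """
    m = np.asarray(metabolite_peaks, dtype=float) % 24.0
    t = np.asarray(transcript_peaks, dtype=float) % 24.0
    if len(m) != len(t):
        raise ValueError("peak arrays must align")
    if len(m) < 3:
        raise ValueError("need >= 3 pairs for association analysis")
    lags = circular_lag(m, t)
    if np.allclose(m, m[0]) or np.allclose(t, t[0]):
        pearson_r, pearson_p = math.nan, math.nan
    else:
        res = stats.pearsonr(m, t)
        pearson_r, pearson_p = float(res.statistic), float(res.pvalue)
    circ_r, circ_p = _circ_corr(m * 2 * np.pi / 24.0, t * 2 * np.pi / 24.0)
    edges = np.arange(-12.0, 12.0 + bin_width, bin_width)
    hist, _ = np.histogram(np.asarray(lags), bins=edges)
    return {
        "pearson_r": pearson_r,
        "pearson_p": pearson_p,
        "circular_r": circ_r,
        "circular_p": circ_p,
        "lags": np.asarray(lags),
        "lag_bin_edges": edges,
        "lag_hist": hist,
    }
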