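"""End-to-end orchestration: quantify -> rhythm -> budget -> linkage -> multivariate."""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, budget, linkage, multivariate, quantify, rhythm
from .io import PipelineConfig, read_table, write_table

logger = logging.getLogger(__name__)

__all__ = ["StageError", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _param_hash(cfg: PipelineConfig) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _compound_infos(df: pd.DataFrame) -> list[quantify.CompoundInfo]:
    return [
        quantify.CompoundInfo(
            name=r["compound"],
            n_carbon=int(r["n_carbon"]),
            n_nitrogen=int(r["n_nitrogen"]),
            kegg_compound_id=r.get("kegg_compound_id") if pd.notna(r.get("kegg_compound_id")) else None,
            osmolyte=bool(r.get("osmolyte", False)),
            quant_mode=r["quant_mode"],
            isotopologue_partner=r.get("isotopologue_partner")
            if pd.notna(r.get("isotopologue_partner"))
            else None,
            underestimate_flag=bool(r.get("underestimate_flag", False)),
        )
        for _, r in df.iterrows()
    ]


def run_pipeline(cfg: PipelineConfig, stages: tuple[str, ...] | None = None) -> dict:
    """Execute the analysis described by ``cfg``.

    Writes all output tables plus ``manifest.json`` into ``cfg.out_dir``
    and returns the result bundle as a dict of DataFrames.  ``stages``
    restricts execution to the named subset (callers must include
    prerequisites); any stage failure raises :class:`StageError` naming
    the stage.
    """
    selected = set(stages) if stages is not None else None
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    manifest: dict = {
        "dielmet_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg.seed,
        "param_hash": _param_hash(cfg),
        "parameters": asdict(cfg),
        "stages": [],
    }

    def stage(name):
        def deco(fn):
            if selected is not None and name not in selected:
                manifest["stages"].append({"name": name, "status": "skipped"})
                return
            try:
                fn()
                manifest["stages"].append({"name": name, "status": "ok"})
            except Exception as err:  # noqa: BLE001 - re-raised with stage context
                manifest["stages"].append({"name": name, "status": "failed", "error": str(err)})
                (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
                raise StageError(name, err) from err
        return deco

    state: dict = {}

    @stage("read_inputs")
    def _read():
        state["samples"] = read_table(cfg.path("samples"), "samples")
        state["areas"] = read_table(cfg.path("areas"), "areas")
        state["is_areas"] = read_table(cfg.path("is_areas"), "is_areas")
        state["compounds"] = read_table(cfg.path("compounds"), "compounds")
        state["is_spikes"] = read_table(cfg.path("is_spikes"), "is_spikes")
        state["additions"] = (
            read_table(cfg.path("additions"), "additions")
            if cfg.path("additions").exists()
            else None
        )
        state["external_standards"] = (
            read_table(cfg.path("external_standards"), "external_standards")
            if cfg.path("external_standards").exists()
            else None
        )
        state["covariates"] = (
            read_table(cfg.path("covariates"), "covariates")
            if cfg.path("covariates").exists()
            else None
        )
        state["transcripts"] = read_table(cfg.path("transcripts"), "transcripts")
        state["links"] = (
            read_table(cfg.path("links"), "links") if cfg.links else linkage.default_links()
        )
        state["quotas"] = (
            read_table(cfg.path("quotas"), "quotas") if cfg.path("quotas").exists() else None
        )

    @stage("quantify")
    def _quantify():
        infos = _compound_infos(state["compounds"])
        spikes = dict(
            zip(state["is_spikes"]["internal_standard"], state["is_spikes"]["spike_pmol"])
        )
        conc = quantify.quantify_study(
            state["areas"],
            state["is_areas"],
            state["samples"],
            infos,
            spikes,
            additions=state["additions"],
            external_standards=state["external_standards"],
            min_improvement=cfg.min_improvement,
            blank_ratio=cfg.blank_ratio,
        )
        state["infos"] = {i.name: i for i in infos}
        results["concentrations"] = conc
        write_table(conc, out / "concentrations.csv")

    @stage("rhythm_metabolites")
    def _rhythm_met():
        conc = results["concentrations"].rename(
            columns={"compound": "signal_id", "pmol_per_L": "value"}
        )[["signal_id", "sample_id", "value"]]
        res = rhythm.classify_signals(
            conc,
            state["samples"],
            interval=cfg.sampling_interval,
            alpha=cfg.alpha,
            harmonics=cfg.harmonics,
            window_start_hour=cfg.window_start_hour,
        )
        results["rhythm_metabolites"] = res
        write_table(res, out / "rhythm_results.csv")

    @stage("rhythm_transcripts")
    def _rhythm_tr():
        agg, _ = linkage.aggregate_transcripts(state["transcripts"])
        agg = agg.assign(signal_id=agg["taxon"] + "|" + agg["ko_id"].astype(str))
        tr = agg.rename(columns={"abundance": "value"})[["signal_id", "sample_id", "value"]]
        # transcripts are single casts; replicate observations per phase
        # class come from pooling days, so the same classifier applies
        res = rhythm.classify_signals(
            tr,
            state["samples"],
            interval=cfg.sampling_interval,
            alpha=cfg.alpha,
            harmonics=cfg.harmonics,
            window_start_hour=cfg.window_start_hour,
        )
        parts = res["signal_id"].str.split("|", n=1, expand=True)
        res = res.assign(taxon=parts[0], ko_id=parts[1])
        dom = agg.drop_duplicates("signal_id").set_index("signal_id")
        if "domain" in dom.columns:
            res = res.assign(domain=res["signal_id"].map(dom["domain"]))
        results["rhythm_transcripts"] = res
        write_table(res, out / "rhythm_transcripts.csv")

    @stage("budget")
    def _budget():
        conc = results["concentrations"].merge(
            state["samples"][["sample_id", "t_hours", "clock_hour", "period"]],
            on="sample_id",
        )
        p1 = conc[conc["period"].astype(str) == conc["period"].astype(str).min()]
        med = (
            p1.groupby(["compound", "t_hours"], as_index=False)["pmol_per_L"]
            .median()
            .rename(columns={"pmol_per_L": "value"})
        )
        scope = results["rhythm_metabolites"]
        scope1 = scope[scope["scope"] == scope["scope"].min()]
        diel = scope1.loc[scope1["is_diel"], "signal_id"].tolist()
        include = None if cfg.include_all_in_totals else diel
        spw = int(round(24.0 / cfg.sampling_interval))
        flux, totals = budget.net_turnover(med, state["infos"], spw, include=include)
        results["flux"] = flux
        results["flux_totals"] = totals
        write_table(flux, out / "flux.csv")

        rows = []
        if state["covariates"] is not None:
            poc = float(state["covariates"]["poc_umol"].mean())
            pn = float(state["covariates"]["pn_umol"].mean())
            for name, grp in med.groupby("compound"):
                info = state["infos"].get(name)
                if info is None:
                    continue
                mean_conc = float(grp["value"].mean())
                pct_poc, pct_pn = budget.composition_fraction(
                    mean_conc, info, poc, pn if pn > 0 else None
                )
                rows.append(
                    {"compound": name, "mean_pmol_per_L": mean_conc,
                     "pct_poc": pct_poc, "pct_pn": pct_pn}
                )
        comp = pd.DataFrame(rows)
        results["composition"] = comp
        write_table(comp, out / "budget.csv")

        att_rows = []
        if state["quotas"] is not None and state["covariates"] is not None:
            cov = state["covariates"]
            for _, q in state["quotas"].iterrows():
                col = f"{q['taxon']}_cells_per_L"
                if col not in cov.columns or q["compound"] not in set(med["compound"]):
                    continue
                series = med[med["compound"] == q["compound"]].sort_values("t_hours")
                cov_sub = cov.set_index("t_hours").reindex(series["t_hours"])
                prof = budget.QuotaProfile(
                    q["taxon"], q["quota_light_fmol"], q["quota_dark_fmol"],
                    cov_sub[col].to_numpy(),
                    cov_sub.get(f"{q['taxon']}_ugC_per_L", pd.Series(dtype=float)).to_numpy()
                    if f"{q['taxon']}_ugC_per_L" in cov_sub.columns else None,
                )
                att = budget.quota_attribution(
                    series["value"].to_numpy(), prof,
                    molar_mass=q.get("molar_mass"),
                )
                for i, t in enumerate(series["t_hours"]):
                    att_rows.append(
                        {
                            "taxon": q["taxon"], "compound": q["compound"], "t_hours": t,
                            "pool_pmol_per_L": series["value"].iloc[i],
                            "predicted_low_pmol": att["predicted_low"][i],
                            "predicted_high_pmol": att["predicted_high"][i],
                            "field_quota_fmol": att["field_quota_fmol"][i],
                        }
                    )
        att_df = pd.DataFrame(att_rows)
        results["attribution"] = att_df
        write_table(att_df, out / "attribution.csv")

    @stage("linkage")
    def _linkage():
        met = results["rhythm_metabolites"]
        met1 = met[met["scope"] == met["scope"].min()]
        tr = results["rhythm_transcripts"]
        tr1 = tr[tr["scope"] == tr["scope"].min()]
        joined, per_met, unlinked = linkage.link_and_classify(state["links"], tr1, met1)
        results["linkage"] = joined
        results["linkage_summary"] = per_met
        results["unlinked"] = unlinked
        write_table(joined, out / "linkage.csv")
        both = joined[
            joined["metabolite_is_diel"].astype(bool)
            & joined["transcript_is_diel"].astype(bool)
        ].dropna(subset=["lag_hours"])
        write_table(
            both[["metabolite", "taxon", "ko_id", "role",
                  "metabolite_peak_hour", "transcript_peak_hour", "lag_hours"]],
            out / "lags.csv",
        )
        if len(both) >= 3:
            assoc = linkage.peak_time_association(
                both["metabolite_peak_hour"].to_numpy(),
                both["transcript_peak_hour"].to_numpy(),
            )
            results["association"] = {
                k: assoc[k] for k in ("pearson_r", "pearson_p", "circular_r", "circular_p")
            }

    @stage("multivariate")
    def _multivariate():
        conc = results["concentrations"].merge(
            state["samples"][["sample_id", "clock_hour", "period"]], on="sample_id"
        )
        p1 = conc[conc["period"].astype(str) == conc["period"].astype(str).min()]
        wide = p1.pivot_table(
            index="compound", columns="sample_id", values="pmol_per_L", aggfunc="first"
        )
        groups = (
            p1.drop_duplicates("sample_id").set_index("sample_id").loc[wide.columns, "clock_hour"]
        )
        dm = multivariate.standardize_and_distance(wide, metric=cfg.metric)
        r, p = multivariate.anosim(
            dm, groups.to_numpy(), n_permutations=cfg.n_permutations, seed=cfg.seed
        )
        results["anosim"] = {"R": r, "p": p, "metric": cfg.metric}
        write_table(pd.DataFrame([results["anosim"]]), out / "anosim.csv")
        pw = multivariate.pairwise_anosim(
            dm, groups.to_numpy(), n_permutations=cfg.n_permutations, seed=cfg.seed
        )
        write_table(pw, out / "pairwise_anosim.csv")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    results["manifest"] = manifest
    return results
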