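"""Configuration-driven orchestration of the full quantification workflow.

Order of stages mirrors the analysis protocol: input-function construction
(calibration, Hill parent-fraction fit, metabolite correction), compartment
fits with optional parameter fixing, AIC model preference, %SE reliability
filtering, graphical methods and SUV, method-comparison regressions, GM/WM
and lesion-vs-NAWM statistics.  Every stochastic stage consumes the config
seed, so a run is fully reproducible from its config.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import simulate as sim
from .data import (
    StudyDataset,
    SubjectData,
    SubjectMeta,
    read_blood_tables,
    read_tac_table,
    write_blood_tables,
    write_tac_table,
)
from .graphical import mlair1, mlair2, patlak, suv
from .input_function import build_input, calibrate_continuous_blood, fit_parent_fraction
from .kinetics import PreparedInput, fit_model
from .stats import (
    LesionClass,
    LesionDescriptor,
    classify_lesion,
    compare_methods,
    filter_reliable,
    group_difference,
    lesion_vs_nawm,
    model_preference,
)

log = logging.getLogger(__name__)


class SimulateSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_hc: int = 2
    n_ms: int = 2
    n_gm_regions: int = 3
    n_wm_regions: int = 3
    lesion_counts: dict[str, int] = Field(
        default_factory=lambda: {"BH": 4, "DM": 4, "PM": 4, "RM": 2})
    noise_alpha: float = 0.3
    truth_model: str = "2T3k"


class PipelineConfig(BaseModel):
    """Validated end-to-end run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    simulate: SimulateSpec | None = None
    input_dir: str | None = None
    models: list[str] = Field(default_factory=lambda: ["1T2k", "2T3k", "2T4k"])
    fix_vb: float | None = None
    fix_k1k2_to_wm: bool = True
    tstar: float = 20.0
    suv_windows: list[tuple[float, float]] = Field(
        default_factory=lambda: [(40.0, 50.0), (50.0, 60.0)])
    se_threshold: float = 25.0
    weights: str = "decay_duration"
    n_starts: int = 3
    out_dir: str | None = None
    seed: int = 0

    def validate_ready(self) -> None:
        if not self.models:
            raise ValueError("config lists no models")
        if self.simulate is None and self.input_dir is None:
            raise ValueError("either a simulate spec or an input_dir is required")


# ---------------------------------------------------------------------------
# Study persistence (the CSV/JSON layout emitted by `medastac simulate`)

def save_study(ds: StudyDataset, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    index = {"subjects": sorted(ds.subjects), "provenance": ds.provenance}
    (out / "study.json").write_text(json.dumps(index, indent=1))
    for sid, s in ds.subjects.items():
        write_tac_table(out / f"{sid}_tacs.csv", s.tacs, subject_id=sid)
        write_blood_tables(out / f"{sid}_blood_continuous.csv",
                           out / f"{sid}_blood_samples.csv",
                           s.continuous_time, s.continuous_blood, s.samples)
        s.meta.to_json(out / f"{sid}_meta.json")
        if s.lesions is not None:
            s.lesions.to_csv(out / f"{sid}_lesions.csv", index=False, float_format="%.9g")


def load_study(in_dir) -> StudyDataset:
    src = Path(in_dir)
    index = json.loads((src / "study.json").read_text())
    subjects = {}
    for sid in index["subjects"]:
        tacs = read_tac_table(src / f"{sid}_tacs.csv")
        t, wb, samples = read_blood_tables(
            src / f"{sid}_blood_continuous.csv", src / f"{sid}_blood_samples.csv")
        lesions_path = src / f"{sid}_lesions.csv"
        subjects[sid] = SubjectData(
            SubjectMeta.from_json(src / f"{sid}_meta.json"),
            tacs, t, wb, samples,
            lesions=pd.read_csv(lesions_path) if lesions_path.exists() else None,
        )
    return StudyDataset(subjects, provenance=index.get("provenance", {}))


@dataclasses.dataclass
class ResultsBundle:
    fits: pd.DataFrame
    preference: pd.DataFrame
    comparisons: pd.DataFrame
    gm_wm: pd.DataFrame
    lesion_stats: pd.DataFrame
    region_status: pd.DataFrame
    input_summary: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return dataclasses.asdict(self)


def _prepare_subject(s: SubjectData):
    """Input-function construction for one subject."""
    f, _ = calibrate_continuous_blood(s.continuous_time, s.continuous_blood, s.samples)
    hill = fit_parent_fraction(s.samples.sample_time, s.samples.parent_fraction)
    inp = build_input(s.continuous_time, f * s.continuous_blood, s.samples, hill)
    return inp, f, hill


def run_quantification(config: PipelineConfig) -> ResultsBundle:
    """Execute the full workflow and (optionally) write tidy CSV outputs."""
    config.validate_ready()
    if config.simulate is not None:
        spec = sim.CohortSpec(
            n_hc=config.simulate.n_hc, n_ms=config.simulate.n_ms,
            n_gm_regions=config.simulate.n_gm_regions,
            n_wm_regions=config.simulate.n_wm_regions,
            lesion_counts=config.simulate.lesion_counts,
            noise_alpha=config.simulate.noise_alpha,
            truth_model=config.simulate.truth_model,
            seed=config.seed,
        )
        ds, _truth = sim.generate_cohort(spec)
    else:
        ds = load_study(config.input_dir)

    fit_rows, input_rows, status_rows, simp_rows = [], [], [], []
    lesion_tables = []
    for sid in sorted(ds.subjects):
        s = ds.subjects[sid]
        try:
            inp, f, hill = _prepare_subject(s)
        except Exception as exc:
            raise RuntimeError(f"input-function stage failed for {sid}: {exc}") from exc
        input_rows.append({
            "subject": sid, "calibration_factor": f,
            "hill_a": hill.a, "hill_b": hill.b, "hill_c": hill.c,
            "parent_fraction_10min": float(hill.parent_fraction(10.0)),
        })
        prep = PreparedInput(inp, s.tacs[0].schedule)

        # whole-brain WM ratio for the K1/k2-fixed lesion mode
        wm_ratio = None
        if config.fix_k1k2_to_wm:
            wm_tac = next((t for t in s.tacs if t.region_label == "whole_brain_WM"), None)
            if wm_tac is not None:
                wm_fit = fit_model(wm_tac, prep, "2T3k", weights_mode=config.weights,
                                   n_starts=config.n_starts, jitter_seed=config.seed)
                wm_ratio = wm_fit.params.K1 / wm_fit.params.k2

        lesion_regions = set()
        if s.lesions is not None:
            lesion_regions = set(s.lesions["region"])

        for tac in s.tacs:
            status = "fitted"
            for model in config.models:
                fixed = {} if config.fix_vb is None else {"VB": config.fix_vb}
                ratio = wm_ratio if (model == "2T3k" and tac.region_label in lesion_regions) else None
                try:
                    fr = fit_model(tac, prep, model, fixed=fixed, k1k2_ratio=ratio,
                                   weights_mode=config.weights,
                                   n_starts=config.n_starts, jitter_seed=config.seed)
                except Exception as exc:
                    log.warning("fit failed (%s, %s, %s): %s", sid, tac.region_label, model, exc)
                    status = "failed"
                    continue
                row = {
                    "subject": sid, "region": tac.region_label,
                    "tissue_class": tac.tissue_class.value, "model": model,
                    "fixing": "k1k2_wm" if ratio is not None else ("vb" if fixed else "none"),
                    **fr.params.as_dict(), **{f"se_pct_{k}": v for k, v in fr.se_percent.items()},
                    "Ki": fr.macro.Ki if fr.macro.Ki is not None else math.nan,
                    "VT": fr.macro.VT if fr.macro.VT is not None else math.nan,
                    "BPND": fr.macro.BPND if fr.macro.BPND is not None else math.nan,
                    "wrss": fr.wrss, "r2": fr.r2, "aic": fr.aic,
                }
                fit_rows.append(row)
            # simplified methods
            try:
                pat = patlak(tac, inp, config.tstar)
                m1 = mlair1(tac, inp)
                m2 = mlair2(tac, inp)
                srow = {
                    "subject": sid, "region": tac.region_label,
                    "tissue_class": tac.tissue_class.value,
                    "patlak_Ki": pat.estimate, "mlair1_Ki": m1.estimate,
                    "mlair2_Ki": m2.estimate,
                }
                for w0, w1 in config.suv_windows:
                    srow[f"suv_{w0:g}_{w1:g}"] = suv(tac, (w0, w1), s.meta).suv
                simp_rows.append(srow)
            except Exception as exc:
                log.warning("simplified methods failed (%s, %s): %s", sid, tac.region_label, exc)
                status = "failed" if status == "failed" else "simplified_failed"
            status_rows.append({"subject": sid, "region": tac.region_label, "status": status})

        if s.lesions is not None:
            lt = s.lesions.copy()
            lt["assigned_class"] = [
                classify_lesion(LesionDescriptor(
                    r.lesion_id, bool(r.flair_hyper), r.t1_class, bool(r.gd_hyper),
                    r.vol_t1_ml, r.vol_flair_ml, r.max_diam_mm, r.nawm_region)).value
                for r in lt.itertuples()
            ]
            lt["subject"] = sid
            lesion_tables.append(lt)

    fits = pd.DataFrame(fit_rows)
    simplified = pd.DataFrame(simp_rows)
    status = pd.DataFrame(status_rows)
    input_summary = pd.DataFrame(input_rows)

    # AIC preference per tissue class (unfixed fits only)
    pref_df = pd.DataFrame()
    if not fits.empty and fits["model"].nunique() >= 2:
        base = fits[fits["fixing"] == "none"].copy()
        base["region"] = base["subject"] + "/" + base["region"]
        pref = model_preference(base[["region", "model", "aic", "tissue_class"]],
                                group_col="tissue_class")
        pref_df = pref.percentages.reset_index(names="tissue_class")

    # reliability filter + method comparison on 2T3k Ki
    comparisons = pd.DataFrame()
    gm_wm = pd.DataFrame()
    lesion_stats = pd.DataFrame()
    if not fits.empty and "2T3k" in set(fits["model"]) and not simplified.empty:
        k2t3k = fits[(fits["model"] == "2T3k")].copy()
        k2t3k["se_percent"] = k2t3k["se_pct_Ki"]
        kept, removed = filter_reliable(k2t3k, config.se_threshold)
        log.info("reliability filter removed %.1f%% of 2T3k Ki estimates", 100 * removed)
        merged = kept.merge(simplified, on=["subject", "region", "tissue_class"])
        merged["cohort"] = merged["subject"].str[:2]
        comp_rows = []
        cand_cols = [c for c in merged.columns
                     if c.startswith(("patlak", "mlair", "suv_"))]
        for grp, gsub in (("HC", merged[merged.cohort == "HC"]),
                          ("MS", merged[merged.cohort == "MS"]),
                          ("all", merged)):
            if len(gsub) < 3:
                continue
            for cand in cand_cols:
                try:
                    c = compare_methods(gsub["Ki"], gsub[cand], group=grp)
                except ValueError:
                    continue
                comp_rows.append({"group": grp, "method": cand, "r": c.r,
                                  "slope": c.slope, "intercept": c.intercept, "n": c.n})
        comparisons = pd.DataFrame(comp_rows)

        hc = merged[(merged.cohort == "HC")]
        gm = hc.loc[hc.tissue_class == "GM", "Ki"]
        wm = hc.loc[hc.tissue_class == "WM", "Ki"]
        if gm.size >= 3 and wm.size >= 3:
            res = group_difference(gm, wm)
            gm_wm = pd.DataFrame([{"parameter": "2T3k_Ki", "gm_mean": gm.mean(),
                                   "gm_sd": gm.std(ddof=1), "wm_mean": wm.mean(),
                                   "wm_sd": wm.std(ddof=1), **{k: v for k, v in res.items()
                                                               if k in ("t", "df", "p", "test_used")}}])

        if lesion_tables:
            lesions = pd.concat(lesion_tables, ignore_index=True)
            lesions["skey"] = lesions["subject"] + "/" + lesions["region"]
            merged["skey"] = merged["subject"] + "/" + merged["region"]
            ki_by_region = merged.set_index("skey")["Ki"]
            rows = []
            for cls in [c.value for c in LesionClass if c not in
                        (LesionClass.ACTIVE, LesionClass.EXCLUDED)]:
                sub = lesions[lesions["assigned_class"] == cls]
                if sub.empty:
                    continue
                lv, nv = [], []
                for r in sub.itertuples():
                    lkey, nkey = r.skey, f"{r.subject}/{r.nawm_region}"
                    if lkey in ki_by_region.index and nkey in ki_by_region.index:
                        lv.append(ki_by_region[lkey])
                        nv.append(ki_by_region[nkey])
                if len(lv) >= 1 and len(nv) >= 1:
                    res = lesion_vs_nawm(lv, nv)
                    rows.append({"lesion_class": cls, "n": len(lv),
                                 "lesion_Ki_mean": float(np.mean(lv)),
                                 "nawm_Ki_mean": float(np.mean(nv)),
                                 "U": res["U"], "p": res["p"]})
            lesion_stats = pd.DataFrame(rows)

    bundle = ResultsBundle(fits, pref_df, comparisons, gm_wm, lesion_stats, status, input_summary)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in bundle.tables().items():
            pd.DataFrame(df).to_csv(out / f"{name}.csv", index=False, float_format="%.9g")
        simplified.to_csv(out / "simplified.csv", index=False, float_format="%.9g")
        (out / "run_log.json").write_text(json.dumps(
            {"seed": config.seed, "models": config.models,
             "n_subjects": len(ds.subjects)}, indent=1))
    return bundle


def sweep_tstar(config: PipelineConfig, tstar_list) -> pd.DataFrame:
    """Patlak Ki per region per start time, with bias vs the 2T3k Ki."""
    tstars = list(tstar_list)
    if len(tstars) < 2:
        raise ValueError("need at least 2 tstar values")
    config.validate_ready()
    if config.simulate is not None:
        spec = sim.CohortSpec(n_hc=config.simulate.n_hc, n_ms=0,
                              n_gm_regions=config.simulate.n_gm_regions,
                              n_wm_regions=config.simulate.n_wm_regions,
                              noise_alpha=config.simulate.noise_alpha,
                              truth_model=config.simulate.truth_model, seed=config.seed)
        ds, _ = sim.generate_cohort(spec)
    else:
        ds = load_study(config.input_dir)
    rows = []
    for sid in sorted(ds.subjects):
        s = ds.subjects[sid]
        inp, _, _ = _prepare_subject(s)
        prep = PreparedInput(inp, s.tacs[0].schedule)
        for tac in s.tacs:
            ref = fit_model(tac, prep, "2T3k", weights_mode=config.weights,
                            n_starts=config.n_starts, jitter_seed=config.seed)
            for ts in tstars:
                if ts >= tac.schedule.frame_end[-1]:
                    raise ValueError(f"tstar {ts} beyond scan end")
                ki = patlak(tac, inp, ts).estimate
                rows.append({"subject": sid, "region": tac.region_label, "tstar": ts,
                             "patlak_Ki": ki, "ref_2T3k_Ki": ref.macro.Ki,
                             "bias_pct": 100.0 * (ki - ref.macro.Ki) / ref.macro.Ki})
    return pd.DataFrame(rows)
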