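"""End-to-end orchestration: phantoms/cohort → segmentation → features →
reference uptake → cohort statistics, with a reproducibility manifest.

One global seed fans out to fixed per-stage child seeds so any stage can be
re-run in isolation and a run is fully determined by (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import traceback
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Cohort, CohortSpec, generate_cohort
from .phantom import default_phantom_spec, generate_phantom
from .radiomics import FEATURE_NAMES, HistogramConfig, extract_features
from .reference_uptake import VERTEBRAL_VOI_DIAMETER_MM, measure_reference_uptake
from .segmentation import SegmentationConfig, delineate_tumor
from .volume import SUVVolume, sphere_mask

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_pipeline"]

STAGES = ("simulate", "segment", "features", "refuptake", "stats")

#: candidate covariates of the survival screen, with the per-unit scalings
#: under which hazard ratios are reported
SURVIVAL_CANDIDATES = (
    "tnm_stage_34",
    "max_suv",
    "mtv_cm3",
    "tlg_g",
    "mean_suv",
    "median_suv",
    "cov_suv",
    "kurtosis",
    "skewness",
    "entropy_bits",
    "uniformity",
    "bm_suv",
    "blr",
    "spleen_suv",
    "slr",
)


def _child_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (JSON-serializable)."""

    outdir: str = "petimm_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    n_phantoms: int = 5
    cohort_n_patients: int = 119
    alpha: float = 0.05
    cov_cutoff: float = 0.25
    slr_cutoff: float = 0.83
    dunn_adjustment: str = "none"
    significance_band: float = 0.10  # borderline-significance reporting tier
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    histogram: HistogramConfig = field(default_factory=HistogramConfig)
    save_nifti: bool = False
    make_plots: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        if "segmentation" in raw:
            raw["segmentation"] = SegmentationConfig(**raw["segmentation"])
        if "histogram" in raw:
            raw["histogram"] = HistogramConfig(**raw["histogram"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunReport:
    outdir: str
    manifest: dict
    phantom_features: pd.DataFrame | None = None
    cohort: Cohort | None = None
    stats: dict | None = None


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def _stage_simulate(config: RunConfig, out: Path, state: dict) -> None:
    seed = _child_seed(config.seed, "simulate")
    phantoms = []
    for k in range(config.n_phantoms):
        spec = default_phantom_spec(seed=(seed + k) % 2**31)
        vol, truth = generate_phantom(spec)
        phantoms.append((spec, vol, truth))
        if config.save_nifti:
            vol.save(out / f"phantom_{k:03d}.nii.gz")
            truth.tumor_mask.save(out / f"phantom_{k:03d}_tumor_truth.nii.gz")
            _dump_json(truth.to_index(), out / f"phantom_{k:03d}_truth.json")
    state["phantoms"] = phantoms

    cohort = generate_cohort(
        CohortSpec(n_patients=config.cohort_n_patients, seed=_child_seed(config.seed, "cohort"))
    )
    cohort.to_csv(out / "cohort.csv")
    state["cohort"] = cohort


def _stage_segment(config: RunConfig, out: Path, state: dict) -> None:
    rows = []
    for k, (spec, vol, truth) in enumerate(state["phantoms"]):
        res = delineate_tumor(
            vol,
            spec.tumor_center_mm,
            config.segmentation,
            organ_masks=tuple(truth.organ_masks.values()),
        )
        state.setdefault("tumor_masks", {})[k] = res
        rows.append(
            {
                "phantom": k,
                "threshold": res.threshold,
                "iterations": res.iterations,
                "converged": res.converged,
                "background_mean": res.background_mean,
                "mtv_cm3": res.mask.volume_cm3,
                "true_volume_cm3": truth.true_tumor_volume_cm3,
            }
        )
        if config.save_nifti:
            res.mask.save(out / f"phantom_{k:03d}_tumor_seg.nii.gz")
    pd.DataFrame(rows).to_csv(out / "segmentation.csv", index=False)


def _stage_features(config: RunConfig, out: Path, state: dict) -> None:
    rows = []
    for k, (spec, vol, truth) in enumerate(state["phantoms"]):
        feats = extract_features(vol, state["tumor_masks"][k].mask, config.histogram)
        rows.append({"phantom": k, **feats.as_dict()})
    state["phantom_features"] = pd.DataFrame(rows)
    state["phantom_features"].to_csv(out / "phantom_features.csv", index=False)


def _stage_refuptake(config: RunConfig, out: Path, state: dict) -> None:
    rows = []
    for k, (spec, vol, truth) in enumerate(state["phantoms"]):
        vois = [
            sphere_mask(
                vol,
                next(o.center_mm for o in spec.organ_specs if o.label == f"vertebra_{i}"),
                VERTEBRAL_VOI_DIAMETER_MM / 2.0,
                label=f"vertebra_{i}",
            )
            for i in range(1, 7)
        ]
        liver = next(o.center_mm for o in spec.organ_specs if o.label == "liver")
        spleen = next(o.center_mm for o in spec.organ_specs if o.label == "spleen")
        ref = measure_reference_uptake(vol, vois, liver, spleen)
        rows.append({"phantom": k, **ref.as_dict()})
    df = pd.DataFrame(rows)
    df.to_csv(out / "phantom_reference_uptake.csv", index=False)
    if state.get("phantom_features") is not None:
        merged = state["phantom_features"].merge(df, on="phantom")
        merged.to_csv(out / "phantom_features.csv", index=False)
        state["phantom_features"] = merged


def _stage_stats(config: RunConfig, out: Path, state: dict) -> None:
    from . import stats as st

    cohort = state["cohort"]
    df = cohort.records.copy()
    df["tnm_stage_34"] = df["tnm_stage"].isin(["III", "IV"]).astype(float)
    cohort = Cohort(df, provenance=cohort.provenance)

    # feature-vs-grade associations (Kruskal-Wallis, Dunn post hoc on significant ones)
    grade_rows = []
    markers = ("cd4", "cd8", "cd163", "il6", "mmp11")
    features = list(FEATURE_NAMES) + ["bm_suv", "spleen_suv", "blr", "slr"]
    for marker in markers:
        for feat in features:
            kw = st.kruskal_wallis_by_grade(cohort, feat, marker)
            tier = (
                "significant"
                if kw.p_value < config.alpha
                else "borderline"
                if kw.p_value < config.significance_band
                else "ns"
            )
            row = {
                "marker": marker,
                "feature": feat,
                "H": kw.h_statistic,
                "df": kw.df,
                "p": kw.p_value,
                "tier": tier,
            }
            if kw.p_value < config.alpha:
                dunn = st.dunn_posthoc(cohort, feat, marker, adjustment=config.dunn_adjustment)
                row["dunn_p_0_vs_2"] = dunn.p_values[
                    dunn.pairs.index((0, 2)) if (0, 2) in dunn.pairs else 0
                ]
            grade_rows.append(row)
    grade_table = pd.DataFrame(grade_rows)
    grade_table.to_csv(out / "feature_grade_tests.csv", index=False)

    # tumor-grade comparison (Mann-Whitney)
    mw_rows = []
    for feat in features:
        u, p = st.mann_whitney(cohort, feat, "tumor_grade")
        mw_rows.append({"feature": feat, "U": u, "p": p})
    pd.DataFrame(mw_rows).to_csv(out / "tumor_grade_tests.csv", index=False)

    # survival analysis: univariate screen -> multivariate Cox
    candidates = [c for c in SURVIVAL_CANDIDATES if c in df.columns]
    selected, uni = st.univariate_screen(cohort, candidates, alpha=config.alpha)
    uni_table = pd.concat(
        [r.summary_frame() for r in uni.values()], axis=0
    ).reset_index(names="covariate")
    uni_table.to_csv(out / "cox_univariate.csv", index=False)
    multi = None
    if selected:
        multi = st.cox_fit(cohort, selected)
        multi.summary_frame().reset_index(names="covariate").to_csv(
            out / "cox_multivariate.csv", index=False
        )

    # ROC cutoffs and KM curves for the prespecified imaging markers
    cut_cov = st.roc_cutoff(cohort, "cov_suv")
    cut_slr = st.roc_cutoff(cohort, "slr")
    df["cov_group"] = np.where(df["cov_suv"] > config.cov_cutoff, "high_cov", "low_cov")
    df["slr_group"] = np.where(df["slr"] < config.slr_cutoff, "low_slr", "high_slr")
    cohort2 = Cohort(df, provenance=cohort.provenance)
    km_results = {}
    for grouping in ("cov_group", "slr_group"):
        curves, chi2, p = st.km_logrank(cohort2, grouping)
        km_results[grouping] = {
            "chi2": chi2,
            "p": p,
            "groups": {
                g: {"n": c.n, "events": c.events, "rfs_60mo": c.survival_at(60.0)}
                for g, c in curves.items()
            },
        }
        steps = pd.concat(
            [
                pd.DataFrame({"group": g, "time": c.times, "survival": c.survival})
                for g, c in curves.items()
            ]
        )
        steps.to_csv(out / f"km_{grouping}.csv", index=False)
        if config.make_plots:
            _plot_km(curves, p, out / f"km_{grouping}.png")

    strat = st.recurrence_strat_table(cohort, config.cov_cutoff, config.slr_cutoff)
    strat.to_frame().to_csv(out / "recurrence_strat_table.csv", index=False)

    kmf_all = _overall_rfs(df)

    state["stats"] = {
        "n_patients": int(len(df)),
        "n_events": int(df["event"].sum()),
        "event_fraction": float(df["event"].mean()),
        "rfs_60mo_overall": kmf_all,
        "univariate_selected": selected,
        "multivariate": None
        if multi is None
        else {
            c: {
                "coef": multi.coefficients[c],
                "hr": multi.hazard_ratios[c],
                "ci": [multi.ci_lower[c], multi.ci_upper[c]],
                "p": multi.p_values[c],
                "per_unit": multi.scalings[c],
            }
            for c in multi.covariates
        },
        "roc_cutoffs": {
            "cov_suv": {"cutoff": cut_cov.cutoff, "youden_j": cut_cov.youden_j,
                        "direction": cut_cov.direction},
            "slr": {"cutoff": cut_slr.cutoff, "youden_j": cut_slr.youden_j,
                    "direction": cut_slr.direction},
        },
        "km_logrank": km_results,
        "strat_table": {
            f"{sg}|{ig}": cell for (sg, ig), cell in strat.cells.items()
        },
        "feature_grade_significant": grade_table.loc[
            grade_table["tier"] == "significant", ["marker", "feature", "p"]
        ].to_dict("records"),
    }
    _dump_json(state["stats"], out / "stats.json")


def _overall_rfs(df: pd.DataFrame, t: float = 60.0) -> float:
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(df["rfs_months"], df["event"])
    return float(kmf.predict(t))


def _plot_km(curves, p, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for g, c in curves.items():
        ax.step(c.times, c.survival, where="post", label=f"{g} (n={c.n})")
    ax.set_xlabel("months since surgery")
    ax.set_ylabel("recurrence-free survival")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    ax.set_title(f"log-rank p = {p:.3g}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "segment": _stage_segment,
    "features": _stage_features,
    "refuptake": _stage_refuptake,
    "stats": _stage_stats,
}


def run_pipeline(config: RunConfig, cohort: Cohort | None = None) -> RunReport:
    """Execute the enabled stages in order; idempotent for fixed config+seed.

    A pre-built cohort may be supplied for stats-only runs; otherwise the
    ``simulate`` stage generates one.  A stage failure aborts the run with
    the failing stage named and leaves partial outputs under ``failed/``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    state: dict = {}
    if cohort is not None:
        state["cohort"] = cohort

    imaging_needed = {"segment", "features", "refuptake"} & set(config.stages)
    if imaging_needed and "simulate" not in config.stages and "phantoms" not in state:
        raise ValueError("imaging stages require the simulate stage (or pre-loaded phantoms)")

    done = []
    for stage in STAGES:
        if stage not in config.stages:
            continue
        if stage == "stats" and "cohort" not in state:
            raise ValueError("stats stage requires a cohort (run simulate or pass cohort=)")
        try:
            _STAGE_FUNCS[stage](config, out, state)
            done.append(stage)
        except Exception as exc:
            failed = out / "failed"
            failed.mkdir(exist_ok=True)
            (failed / f"{stage}.txt").write_text(traceback.format_exc())
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "petimm_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "stages_run": done,
        "child_seeds": {s: _child_seed(config.seed, s) for s in ("simulate", "cohort")},
    }
    _dump_json(manifest, out / "manifest.json")
    return RunReport(
        outdir=str(out),
        manifest=manifest,
        phantom_features=state.get("phantom_features"),
        cohort=state.get("cohort"),
        stats=state.get("stats"),
    )
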