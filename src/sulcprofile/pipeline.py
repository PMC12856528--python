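"""End-to-end runner: simulate/read -> preprocess -> extract -> density -> stats -> report.

Every stage writes its table into the run directory, and a machine-readable
``manifest.json`` keeps the bookkeeping: profile counts entering and leaving
each filter step, seeds, and stage notices.  Reruns with the same
configuration are deterministic.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import stats as gs
from .extrema import find_turnpoints, kde2d_extrema, density_summary
from .profiles import Cohort, read_cohort, write_cohort, profiles_by_subject
from .smoothing import SmoothingConfig, invert_depths, smooth_profile
from .synthetic import GeneratorConfig, simulate_cohort, groundtruth_table

__all__ = ["PipelineConfig", "StatsConfig", "run_pipeline", "report", "feature_long_tables"]


@dataclass(frozen=True)
class StatsConfig:
    resample_iterations: int = 10_000
    permutation_iterations: int = 10_000
    seed: int = 0
    alpha: float = 0.05
    bonferroni_comparisons: int = 4


@dataclass
class PipelineConfig:
    profiles_path: str | None = None
    metadata_path: str | None = None
    generator: GeneratorConfig | None = None
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    feature: feat.FeatureConfig = field(default_factory=feat.FeatureConfig)
    density_level: float = 0.0025
    stats: StatsConfig = field(default_factory=StatsConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw: dict = {}
        if "profiles" in raw:
            kw["profiles_path"] = raw["profiles"]
        if "metadata" in raw:
            kw["metadata_path"] = raw["metadata"]
        if "generator" in raw:
            g = dict(raw["generator"])
            from .synthetic import BaseCurveConfig, BumpConfig, EffectsConfig, NoiseConfig

            for key, sub in (
                ("base_curve", BaseCurveConfig),
                ("bump", BumpConfig),
                ("effects", EffectsConfig),
                ("noise", NoiseConfig),
            ):
                if key in g:
                    g[key] = sub(**g[key])
            kw["generator"] = GeneratorConfig(**g)
        if "smoothing" in raw:
            s = raw["smoothing"]
            kw["smoothing"] = SmoothingConfig(
                target_effective_df=s.get("df", 20.0),
                penalty_coefficient=s.get("penalty_coefficient", 1.0),
            )
        if "feature" in raw:
            kw["feature"] = feat.FeatureConfig(**raw["feature"])
        if "density_level" in raw:
            kw["density_level"] = float(raw["density_level"])
        if "stats" in raw:
            kw["stats"] = StatsConfig(**raw["stats"])
        return cls(**kw)


def feature_long_tables(ft: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long tables for the statistics battery, complete-case filtered.

    Keeps subjects with both hemispheres present and PPfpm-I extracted in
    both.  Returns (landmarks, extent): landmarks has one row per subject x
    hemisphere x feature(I/II) with position and depth; extent one row per
    subject x hemisphere x dimension (width / relative height, both in %).
    """
    wide = ft.pivot_table(index="subject_id", columns="hemisphere", values="ppfpm1_absent", aggfunc="first")
    if not {"left", "right"}.issubset(wide.columns):
        return pd.DataFrame(), pd.DataFrame()
    ok = wide.index[(wide["left"] == False) & (wide["right"] == False)]  # noqa: E712
    sub = ft[ft["subject_id"].isin(ok)]
    rows_lm, rows_ex = [], []
    for _, r in sub.iterrows():
        base = {
            "subject_id": r["subject_id"],
            "hemisphere": r["hemisphere"],
            "sex": r["sex"],
            "oldfield": r["oldfield"],
            "handedness": r["handedness"],
        }
        rows_lm.append({**base, "feature": "I", "position": r["x_I"], "depth": r["y_I"]})
        rows_lm.append({**base, "feature": "II", "position": r["x_II"], "depth": r["y_II"]})
        rows_ex.append({**base, "dimension": "width", "value": r["width_pct"]})
        rows_ex.append({**base, "dimension": "rel_height", "value": r["rel_height_pct"]})
    return pd.DataFrame(rows_lm), pd.DataFrame(rows_ex)


def _hemi_pairs(landmarks: pd.DataFrame, value: str, feature: str) -> tuple[np.ndarray, np.ndarray]:
    w = landmarks[landmarks["feature"] == feature].pivot_table(
        index="subject_id", columns="hemisphere", values=value
    )
    return w["left"].to_numpy(), w["right"].to_numpy()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "counts": {}, "notices": []}

    # --- stage: input -------------------------------------------------------
    if config.generator is not None:
        cohort, truths = simulate_cohort(config.generator)
        groundtruth_table(truths).to_csv(out / "groundtruth.csv", index=False)
        manifest["stages"].append("simulate")
        manifest["seed"] = config.generator.seed
    elif config.profiles_path and config.metadata_path:
        cohort = read_cohort(config.profiles_path, config.metadata_path)
        manifest["stages"].append("read")
    else:
        raise ValueError("config must give either a generator or input paths")
    write_cohort(cohort, out)
    manifest["counts"]["profiles_in"] = len(cohort)
    active = cohort.active_profiles()
    manifest["counts"]["profiles_excluded"] = len(cohort) - len(active)

    # --- stage: preprocess --------------------------------------------------
    smoothed = [smooth_profile(invert_depths(p), config.smoothing) for p in active]
    manifest["stages"].append("preprocess")
    pd.DataFrame(
        {
            "subject_id": [p.subject_id for p in smoothed],
            "hemisphere": [p.hemisphere.code for p in smoothed],
            **{f"d{i:03d}": [p.depths[i] for p in smoothed] for i in range(101)},
        }
    ).to_csv(out / "smoothed.tsv", sep="\t", index=False, float_format="%.6g")

    # --- stage: extract -----------------------------------------------------
    extrema_per_profile = [find_turnpoints(p) for p in smoothed]
    features = [
        feat.extract_features(p, e, config.feature)
        for p, e in zip(smoothed, extrema_per_profile)
    ]
    ft = feat.feature_table(cohort, features)
    ft.to_csv(out / "features.csv", index=False)
    manifest["stages"].append("extract")
    manifest["counts"]["features_rows"] = len(ft)
    manifest["counts"]["ppfpm1_absent"] = int(ft["ppfpm1_absent"].sum())
    manifest["counts"]["ppfpm2_is_deepest"] = int(ft["ppfpm2_is_deepest"].sum())
    manifest["counts"]["ppfpm2_is_deepest_pct"] = gs.percentage(
        int(ft["ppfpm2_is_deepest"].sum()), len(ft)
    ) if len(ft) else None

    # --- stage: density -----------------------------------------------------
    pooled = [e for ex in extrema_per_profile for e in ex]
    dens_out: dict = {}
    for name, sel in (
        ("maxima", [e for e in pooled if e.kind == "maximum"]),
        ("minima", [e for e in pooled if e.kind == "minimum"]),
        ("global_minima", [e for e in pooled if e.is_global_minimum]),
    ):
        if len(sel) < 2:
            manifest["notices"].append(f"density: too few {name} ({len(sel)})")
            continue
        pos = np.array([e.position for e in sel], dtype=float)
        dep = np.array([e.depth for e in sel], dtype=float)
        if np.ptp(pos) == 0 or np.ptp(dep) == 0:
            manifest["notices"].append(f"density: degenerate spread for {name}")
            continue
        grid = kde2d_extrema(pos, dep)
        summ = density_summary(grid, config.density_level)
        np.savetxt(out / f"density_{name}.csv", grid.density, delimiter=",")
        dens_out[name] = {
            "n": len(sel),
            "peak": {
                "position": summ.peak_position,
                "depth": summ.peak_depth,
                "density": summ.peak_density,
            },
            "level": summ.level,
            "position_range": summ.position_range,
            "depth_range": summ.depth_range,
        }
    (out / "density_summary.json").write_text(json.dumps(dens_out, indent=2))
    manifest["stages"].append("density")

    # --- stage: stats -------------------------------------------------------
    landmarks, extent = feature_long_tables(ft)
    if landmarks.empty:
        manifest["notices"].append("stats skipped: no complete feature pairs")
    elif landmarks["sex"].nunique() < 2 or landmarks["subject_id"].nunique() < 3:
        manifest["notices"].append(
            "stats skipped: needs both sexes and >= 3 complete-case subjects"
        )
    else:
        manifest["stages"].append("stats")
        manifest["counts"]["stats_subjects"] = landmarks["subject_id"].nunique()
        st = config.stats
        for resp in ("position", "depth"):
            res = gs.mixed_anova_3way(landmarks, resp, within=("feature", "hemisphere"), between="sex")
            res.to_frame().to_csv(out / f"anova_{resp}.csv", index=False)
            pairs = [
                (f"PPfpm-I left vs right ({resp})", *_hemi_pairs(landmarks, resp, "I")),
                (f"PPfpm-II left vs right ({resp})", *_hemi_pairs(landmarks, resp, "II")),
            ]
            for hemi in ("left", "right"):
                h = landmarks[landmarks["hemisphere"] == hemi].pivot_table(
                    index="subject_id", columns="feature", values=resp
                )
                pairs.append((f"{hemi}: PPfpm-I vs PPfpm-II ({resp})", h["I"].to_numpy(), h["II"].to_numpy()))
            gs.posthoc_paired_t(pairs, alpha=st.alpha).to_frame().to_csv(
                out / f"posthoc_{resp}.csv", index=False
            )
        res = gs.mixed_anova_3way(extent, "value", within=("dimension", "hemisphere"), between="sex")
        res.to_frame().to_csv(out / "anova_extent.csv", index=False)

        # handedness battery (needs both classes populated)
        subj_old = landmarks.groupby("subject_id")["oldfield"].first().dropna()
        n_left = int((subj_old < 0).sum())
        n_right = int((subj_old > 0).sum())
        if n_left >= 2 and n_right >= 2:
            hand = {}
            for resp in ("position", "depth"):
                rs = gs.balanced_resample_anova(
                    landmarks, resp, iterations=st.resample_iterations, seed=st.seed
                )
                # zero-index subjects are ambiguous and excluded throughout
                lm_tab = landmarks[landmarks["oldfield"] != 0].copy()
                lm_tab["hand"] = np.where(lm_tab["oldfield"] < 0, "left", "right")
                perm = gs.permutation_anova(
                    lm_tab,
                    resp,
                    iterations=st.permutation_iterations,
                    seed=st.seed,
                    between="hand",
                )
                lmm = gs.lmm_random_intercept(
                    lm_tab, resp, fixed="feature * hemisphere * hand"
                )
                hand[resp] = {
                    "resample": {
                        "median_F": rs.median_F,
                        "median_p": rs.median_p,
                        "iterations": rs.iterations,
                        "n_matched": rs.n_matched,
                    },
                    "permutation": {
                        e: {"observed_F": r.observed_F, "b": r.exceed_count, "m": r.iterations, "p": r.p_empirical}
                        for e, r in perm.items()
                    },
                    "lmm": {
                        "beta": lmm.params.to_dict(),
                        "SE": lmm.bse.to_dict(),
                        "t": lmm.tvalues.to_dict(),
                        "var_intercept": lmm.var_intercept,
                        "var_residual": lmm.var_residual,
                        "boundary": lmm.boundary,
                    },
                }
            (out / "handedness.json").write_text(json.dumps(hand, indent=2))
        else:
            manifest["notices"].append(
                f"handedness battery skipped: {n_left} left / {n_right} right"
            )

        corr_in = ft.dropna(subset=["rel_height_pct", "width_pct"])
        if len(corr_in) >= 3:
            corr = gs.pearson_correlation(
                corr_in["rel_height_pct"].to_numpy(), corr_in["width_pct"].to_numpy()
            )
            (out / "correlation.json").write_text(
                json.dumps({"r": corr.r, "p_two_tailed": corr.p_two_tailed, "n": corr.n})
            )
        groups = {
            f"{sex}/{hemi}": g["depth"].to_numpy()
            for (sex, hemi), g in landmarks[landmarks["feature"] == "II"].groupby(["sex", "hemisphere"])
        }
        gs.assumption_checks(groups).to_csv(out / "assumptions.csv", index=False)

    manifest["config"] = json.loads(json.dumps(dataclasses.asdict(config), default=str))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def report(run_dir: str | Path) -> Path:
    """Render a markdown summary (descriptive tables + figures) for a run."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run = Path(run_dir)
    missing = [f for f in ("features.csv", "smoothed.tsv", "manifest.json") if not (run / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run, missing: {', '.join(missing)}")
    ft = pd.read_csv(run / "features.csv")
    sm = pd.read_csv(run / "smoothed.tsv", sep="\t")
    dcols = [c for c in sm.columns if c.startswith("d")]
    curves = sm[dcols].to_numpy()

    lines = ["# Depth-profile run report", ""]
    n = len(ft)
    lines.append(f"Profiles analyzed: {n}; subjects: {ft['subject_id'].nunique()}.")
    both = int((~ft["ppfpm1_absent"]).sum())
    if n:
        lines.append(
            f"Both landmarks extracted in {both}/{n} profiles "
            f"({gs.percentage(both, n)}%); PPfpm-II coincides with the deepest "
            f"point in {gs.percentage(int(ft['ppfpm2_is_deepest'].sum()), n)}%."
        )
    lines.append("")

    def describe(sub: pd.DataFrame, label: str) -> None:
        cols = ["x_I", "y_I", "x_II", "y_II", "abs_height_mm", "rel_height_pct", "width_pct"]
        lines.append(f"## Descriptives: {label}")
        lines.append("")
        lines.append("| metric | mean | SD | SEM | min | max |")
        lines.append("|---|---|---|---|---|---|")
        for c in cols:
            v = sub[c].dropna().to_numpy()
            if v.size == 0:
                lines.append(f"| {c} | - | - | - | - | - |")
                continue
            sd = v.std(ddof=1) if v.size > 1 else float("nan")
            sd_s = f"{sd:.2f}" if np.isfinite(sd) else "undefined (n=1)"
            sem_s = f"{sd / np.sqrt(v.size):.2f}" if np.isfinite(sd) else "undefined (n=1)"
            lines.append(
                f"| {c} | {v.mean():.2f} | {sd_s} | {sem_s} | {v.min():.2f} | {v.max():.2f} |"
            )
        lines.append("")

    describe(ft, "all profiles")
    for sex, sub in sorted(ft.groupby("sex")):
        describe(sub, f"sex = {sex}")

    # figures
    fig, ax = plt.subplots(figsize=(7, 4))
    mean = curves.mean(axis=0)
    sd = curves.std(axis=0, ddof=1) if len(curves) > 1 else np.zeros(curves.shape[1])
    x = np.arange(curves.shape[1])
    for c in curves[: min(len(curves), 200)]:
        ax.plot(x, c, color="steelblue", alpha=0.05, lw=0.5)
    ax.plot(x, mean, color="black", lw=2, label="mean")
    ax.plot(x, mean + sd, "k--", lw=1, label="+/- SD")
    ax.plot(x, mean - sd, "k--", lw=1)
    ax.set_xlabel("position (medial 0 -> lateral 100)")
    ax.set_ylabel("depth [mm]")
    ax.legend()
    fig.tight_layout()
    fig.savefig(run / "fig_average_profile.png", dpi=110)
    plt.close(fig)

    sub = ft.dropna(subset=["rel_height_pct", "width_pct"])
    if len(sub) >= 3:
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(sub["width_pct"], sub["rel_height_pct"], s=8, alpha=0.4)
        b, a = np.polyfit(sub["width_pct"], sub["rel_height_pct"], 1)
        xs = np.linspace(sub["width_pct"].min(), sub["width_pct"].max(), 50)
        ax.plot(xs, a + b * xs, "r-", lw=1.5)
        ax.set_xlabel("peak-to-lateral width [% CS length]")
        ax.set_ylabel("relative height [%]")
        fig.tight_layout()
        fig.savefig(run / "fig_height_width.png", dpi=110)
        plt.close(fig)
        lines.append("## Figures")
        lines.append("")
        lines.append("![average profile](fig_average_profile.png)")
        lines.append("![height vs width](fig_height_width.png)")
        lines.append("")

    out_path = run / "report.md"
    out_path.write_text("\n".join(lines))
    return out_path
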