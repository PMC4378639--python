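"""Group statistics, summary tables and the end-to-end pipeline driver.

Genotype cohorts are summarised as mean +/- SEM per shape metric, in the
layout of the published leaf-parameter table.  The group-level P/sqrt(A) is
reported two ways: the mean of per-leaf proxies, and the ratio of the mean
perimeter to the square root of the mean area — the latter is the
table-comparable column (the published group values are consistent with the
ratio-of-means form, e.g. 36.3/sqrt(90.3) = 3.82 -> 3.8).  Differences
between genotypes are tested with Student's t-test (two-sided, pooled
variance by default; Welch available), with no multiple-testing correction,
matching how the source measurements were analysed.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import morphometry, proliferation, synthetic
from .geometry import ShapeMetrics

__all__ = [
    "GroupSummary",
    "TestResult",
    "summarize_groups",
    "summaries_to_table",
    "students_t",
    "significance_stars",
    "default_config",
    "run_pipeline",
]

METRIC_COLUMNS = ["length", "width", "perimeter", "area", "length_width_ratio", "curvature_proxy"]


@dataclass(frozen=True)
class GroupSummary:
    """Per-genotype mean +/- SEM of the planar shape metrics."""

    genotype: str
    n: int
    mean: Mapping[str, float]
    sem: Mapping[str, float]
    proxy_mean_of_ratios: float
    proxy_ratio_of_means: float
    single_leaf: bool = False


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    comparison: tuple[str, str] = ("x", "y")
    variant: str = "student"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def _sem(x: np.ndarray) -> float:
    if len(x) < 2:
        return 0.0
    return float(x.std(ddof=1) / math.sqrt(len(x)))


def summarize_groups(
    measurements: Mapping[str, Sequence[ShapeMetrics]],
) -> list[GroupSummary]:
    """Mean +/- SEM rows per genotype from per-leaf shape metrics.

    Empty groups are skipped with a warning; single-leaf groups report
    SEM = 0 and are flagged.
    """
    out: list[GroupSummary] = []
    for genotype, metrics in measurements.items():
        metrics = list(metrics)
        if not metrics:
            warnings.warn(f"group {genotype!r} is empty; skipped")
            continue
        df = pd.DataFrame([dataclasses.asdict(m) for m in metrics])
        mean = {c: float(df[c].mean()) for c in METRIC_COLUMNS}
        sem = {c: _sem(df[c].to_numpy()) for c in METRIC_COLUMNS}
        out.append(
            GroupSummary(
                genotype=genotype,
                n=len(metrics),
                mean=mean,
                sem=sem,
                proxy_mean_of_ratios=mean["curvature_proxy"],
                proxy_ratio_of_means=mean["perimeter"] / math.sqrt(mean["area"]),
                single_leaf=len(metrics) == 1,
            )
        )
    return out


def summaries_to_table(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    """Flatten group summaries into a table-shaped DataFrame (1-dp proxies)."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "genotype": s.genotype,
                "length_mm": s.mean["length"],
                "length_sem": s.sem["length"],
                "width_mm": s.mean["width"],
                "width_sem": s.sem["width"],
                "perimeter_mm": s.mean["perimeter"],
                "perimeter_sem": s.sem["perimeter"],
                "area_mm2": s.mean["area"],
                "area_sem": s.sem["area"],
                "length_width_ratio": round(s.mean["length_width_ratio"], 1),
                "lw_sem": s.sem["length_width_ratio"],
                "proxy_ratio_of_means": round(s.proxy_ratio_of_means, 1),
                "proxy_mean_of_ratios": round(s.proxy_mean_of_ratios, 1),
                "proxy_sem": s.sem["curvature_proxy"],
                "n": s.n,
            }
        )
    return pd.DataFrame(rows)


def students_t(
    x: Sequence[float],
    y: Sequence[float],
    variant: str = "student",
    labels: tuple[str, str] = ("x", "y"),
) -> TestResult:
    """Two-sided two-sample t-test (pooled-variance Student or Welch)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        # degenerate: no within-group variance
        p = 1.0 if x.mean() == y.mean() else 0.0
        t = 0.0 if x.mean() == y.mean() else math.inf
        return TestResult(t, float(len(x) + len(y) - 2), p, labels, variant)
    res = stats.ttest_ind(x, y, equal_var=(variant == "student"))
    return TestResult(
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        comparison=labels,
        variant=variant,
    )


def significance_stars(p: float) -> str:
    """Star convention: *** p<=0.001, ** p<=0.01, * p<=0.05, ns otherwise."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------


def default_config() -> dict:
    """Default end-to-end run: wild-type-like and mutant-like cohorts."""
    return {
        "seed": 0,
        "cohorts": {
            "col0": dict(synthetic.COHORT_PRESETS["col0"]),
            "tni": dict(synthetic.COHORT_PRESETS["tni"]),
        },
        "growth": ["col0", "tni"],
        "zones": ["col0", "tni"],
        "fronts": {"col0_like": 11, "tni_like": 5, "jawD_like": 5},
        "front_geometry": {
            "width_mm": 1.0,
            "band_mm": 0.1,
            "cell_area_um2": 160.0,
        },
    }


def run_pipeline(config: dict | str | Path | None = None, outdir: str | Path = "run_out") -> dict:
    """Execute synth -> measure -> profile -> summarize and write TSV outputs.

    ``config`` may be a dict, a YAML file path, or None for the defaults.
    All randomness derives from the root ``seed``.  Returns the report
    bundle as a dict; writes table/growth/zones/fronts TSVs and a JSON run
    log into ``outdir``.
    """
    if config is None:
        config = default_config()
    elif isinstance(config, (str, Path)):
        import yaml

        cfg_path = Path(config)
        if not cfg_path.exists():
            raise FileNotFoundError(f"pipeline config not found: {cfg_path}")
        with open(cfg_path) as fh:
            user = yaml.safe_load(fh) or {}
        config = default_config()
        config.update(user)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root_seed = int(config.get("seed", 0))
    ss = np.random.SeedSequence(root_seed)
    bundle: dict = {"seed": root_seed}

    # --- stage 1: outline cohorts -> shape table -------------------------
    try:
        measurements: dict[str, list[ShapeMetrics]] = {}
        cohort_seeds = ss.spawn(len(config["cohorts"]))
        for (name, preset), seed_seq in zip(config["cohorts"].items(), cohort_seeds):
            rng = np.random.default_rng(seed_seq)
            leaves = []
            for _ in range(preset["n"]):
                L = max(rng.normal(preset["length"], preset["sd_length"]), 0.5)
                W = max(rng.normal(preset["width"], preset["sd_width"]), 0.5)
                spec = synthetic.OutlineSpec(
                    length=L,
                    width=W,
                    roughness=preset.get("roughness", 0.0),
                    seed=int(rng.integers(2**31)),
                    genotype=name,
                )
                outline = synthetic.gen_outline(spec)
                leaves.append(morphometry.measure_outline(outline, axis="x"))
            measurements[name] = leaves
        summaries = summarize_groups(measurements)
        table = summaries_to_table(summaries)
        table.to_csv(outdir / "shape_table.tsv", sep="\t", index=False)
        bundle["shape_table"] = table
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'outlines' failed: {exc}") from exc

    # --- stage 2: growth kinetics ----------------------------------------
    try:
        growth_rows = []
        growth_seeds = ss.spawn(len(config["growth"]))
        for name, seed_seq in zip(config["growth"], growth_seeds):
            spec = dataclasses.replace(
                synthetic.GROWTH_PRESETS[name], seed=int(seed_seq.generate_state(1)[0] % 2**31)
            )
            rates = morphometry.growth_rates(synthetic.gen_growth_series(spec))
            growth_rows.append(
                {"genotype": name, "peak_rate_mm_day": rates.peak_rate, "peak_day": rates.peak_day}
            )
        growth = pd.DataFrame(growth_rows)
        growth.to_csv(outdir / "growth_rates.tsv", sep="\t", index=False)
        bundle["growth"] = growth
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'growth' failed: {exc}") from exc

    # --- stage 3: proliferation-zone dynamics ----------------------------
    try:
        zone_rows = []
        zone_seeds = ss.spawn(len(config["zones"]))
        for name, seed_seq in zip(config["zones"], zone_seeds):
            spec = dataclasses.replace(
                synthetic.ZONE_PRESETS[name], seed=int(seed_seq.generate_state(1)[0] % 2**31)
            )
            slope, r2 = proliferation.zone_slope(synthetic.gen_zone_series(spec))
            zone_rows.append({"genotype": name, "slope_mm_per_mm": slope, "r_squared": r2})
        zones = pd.DataFrame(zone_rows)
        zones.to_csv(outdir / "zone_slopes.tsv", sep="\t", index=False)
        bundle["zones"] = zones
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'zones' failed: {exc}") from exc

    # --- stage 4: arrest-front profiles ----------------------------------
    try:
        geom = config["front_geometry"]
        front_rows = []
        front_seeds = ss.spawn(len(config["fronts"]))
        for (preset, n_leaves), seed_seq in zip(config["fronts"].items(), front_seeds):
            rng = np.random.default_rng(seed_seq)
            model = synthetic.FRONT_PRESETS[preset]
            profiles = []
            for _ in range(n_leaves):
                cmap = synthetic.gen_cell_map(
                    geom["width_mm"], geom["band_mm"], geom["cell_area_um2"],
                    seed=int(rng.integers(2**31)),
                )
                span = proliferation.front_axis_span(cmap.width_um)
                cmap = synthetic.assign_gus(
                    cmap, model, seed=int(rng.integers(2**31)), axis_span=span
                )
                profiles.append(proliferation.fraction_profile(proliferation.bin_fields(cmap)))
            avg = proliferation.average_profiles(profiles)
            label = proliferation.classify_front(avg).label
            for f, frac, se in zip(avg.fields, avg.fractions, avg.se):
                front_rows.append(
                    {
                        "preset": preset,
                        "field_index": f.index_from_midrib,
                        "x_center_um": f.x_center,
                        "n_total": f.n_total,
                        "fraction": frac,
                        "se": se,
                        "classification": label,
                    }
                )
        fronts = pd.DataFrame(front_rows)
        fronts.to_csv(outdir / "front_profiles.tsv", sep="\t", index=False)
        bundle["fronts"] = fronts
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'fronts' failed: {exc}") from exc

    log = {
        "seed": root_seed,
        "config": {k: v for k, v in config.items() if k != "cohorts"},
        "cohorts": {k: dict(v) for k, v in config["cohorts"].items()},
        "outputs": [
            "shape_table.tsv",
            "growth_rates.tsv",
            "zone_slopes.tsv",
            "front_profiles.tsv",
        ],
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1, default=str)
    bundle["log"] = log
    return bundle
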