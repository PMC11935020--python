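"""End-to-end orchestration: generate -> model/fit -> quantify -> compare.

A run is described by a YAML config with a single global seed and one
parameter block per stage.  Each stochastic stage receives its own
reproducible sub-seed derived from the global seed and the stage name
(CRC-32 of the name mixed into a ``SeedSequence``), so stages can be rerun
independently without sharing generator state.

The statistics stage implements the study's pairwise workhorse, the
two-tailed Welch (unequal-variance) t-test, plus the boxplot five-number
summary used to report cohorts.  Multi-group ANOVA/Tukey/Bonferroni
corrections are deliberately left to standard statistical packages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import imagequant, kinetics, rdmodel, synthdata

__all__ = [
    "GroupComparison",
    "RunConfig",
    "welch_t",
    "stage_seed",
    "run",
]

logger = logging.getLogger("juxtacell")

STAGES = ("kinetics", "rdmodel", "synth", "quant", "stats")


class DegenerateVarianceError(ValueError):
    """Both groups have zero variance; the t statistic is undefined."""


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample Welch comparison with boxplot summaries."""

    group_labels: tuple[str, str]
    n: tuple[int, int]
    means: tuple[float, float]
    t_statistic: float
    welch_df: float
    p_two_sided: float
    summary: dict  # per-group: median, q25, q75, whisker_low, whisker_high


def _box_summary(x: np.ndarray) -> dict:
    return {
        "median": float(np.median(x)),
        "q25": float(np.percentile(x, 25)),
        "q75": float(np.percentile(x, 75)),
        "whisker_low": float(x.min()),
        "whisker_high": float(x.max()),
    }


def welch_t(
    a: Sequence[float],
    b: Sequence[float],
    labels: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Two-tailed Welch t-test of two independent samples.

    ``t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b)`` with the
    Welch-Satterthwaite degrees of freedom; p from the t distribution.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            # identical constant groups: no evidence of any difference
            return GroupComparison(
                group_labels=labels,
                n=(a.size, b.size),
                means=(float(a.mean()), float(b.mean())),
                t_statistic=0.0,
                welch_df=float(a.size + b.size - 2),
                p_two_sided=1.0,
                summary={labels[0]: _box_summary(a), labels[1]: _box_summary(b)},
            )
        raise DegenerateVarianceError("both groups have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    se2a, se2b = va / a.size, vb / b.size
    df = (se2a + se2b) ** 2 / (se2a**2 / (a.size - 1) + se2b**2 / (b.size - 1))
    return GroupComparison(
        group_labels=labels,
        n=(a.size, b.size),
        means=(float(a.mean()), float(b.mean())),
        t_statistic=float(res.statistic),
        welch_df=float(df),
        p_two_sided=float(res.pvalue),
        summary={labels[0]: _box_summary(a), labels[1]: _box_summary(b)},
    )


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed: SeedSequence(seed, crc32(stage))."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class RunConfig:
    """Parsed run configuration (see ``run`` for stage semantics)."""

    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    output_dir: str = "juxtacell_out"
    params: dict = field(default_factory=dict)  # per-stage blocks

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            seed=int(raw.get("seed", 0)),
            stages=list(raw.get("stages", STAGES)),
            output_dir=str(raw.get("output_dir", "juxtacell_out")),
            params={k: v for k, v in raw.items() if k in STAGES},
        )

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "stages": list(self.stages),
            "output_dir": self.output_dir,
            **self.params,
        }


def _config_hash(config: RunConfig) -> str:
    # output_dir is a location, not a parameter: same science -> same hash
    payload = {k: v for k, v in config.to_dict().items() if k != "output_dir"}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:16]


def _stage_kinetics(cfg: dict, seed: int, outdir: Path) -> dict:
    K = float(cfg.get("K", 38207.0))
    E_list = [float(e) for e in cfg.get("E_list", [1e-9, 2e-9, 5e-9, 10e-9, 20e-9])]
    noise_cv = float(cfg.get("noise_cv", 0.0))
    traces_file = cfg.get("traces")
    if traces_file:
        traces = kinetics.read_traces_csv(traces_file)
    else:
        traces = synthdata.make_trace_set(K=K, E_list=E_list, noise_cv=noise_cv, seed=seed)
        kinetics.write_traces_csv(traces, outdir / "traces.csv")
    window = cfg.get("window")
    fits = [
        kinetics.fit_log_slope(tr, window=tuple(window) if window else None)
        for tr in traces
    ]
    points = [(tr.enzyme_concentration, f.slope_magnitude) for tr, f in zip(traces, fits)]
    rate = kinetics.estimate_rate_constant(points)
    report = {
        "K_hat": rate.K_hat,
        "ci95": list(rate.ci95),
        "intercept": rate.intercept,
        "r_squared": rate.r_squared,
        "per_trace": [
            {
                "label": tr.label,
                "enzyme_M": tr.enzyme_concentration,
                "slope_magnitude": f.slope_magnitude,
                "r_squared": f.r_squared,
                "n_points_used": f.n_points_used,
                "window": list(f.window),
            }
            for tr, f in zip(traces, fits)
        ],
        "config": {"K_generating": None if traces_file else K, "noise_cv": noise_cv},
    }
    (outdir / "kinetics_fit.json").write_text(json.dumps(report, indent=1))
    return {"K_hat": rate.K_hat, "ci95": list(rate.ci95)}


def _rd_params(cfg: dict) -> rdmodel.RDParams:
    fields = {
        k: cfg[k]
        for k in ("R", "D", "S_tot", "I_tot", "k_on", "Kd_lit", "Kd_dark", "lit", "n_r", "dt")
        if k in cfg
    }
    return rdmodel.RDParams(**fields)


def _stage_rdmodel(cfg: dict, outdir: Path) -> dict:
    params = _rd_params(cfg)
    results = rdmodel.simulate_conditions(
        params,
        tol=float(cfg.get("tol", 1e-6)),
        t_max=float(cfg.get("t_max", 3600.0)),
    )
    rows = []
    for name, res in results.items():
        rows.append(
            {
                "condition": name,
                "ratio": res.ratio,
                "shell_intensity_ratio": res.shell_intensity_ratio,
                "bound_count": res.bound_count,
                "free_count": res.free_count,
                "converged": res.converged,
                "mass_error": res.mass_error,
            }
        )
        prof = pd.DataFrame(
            {"r_um": res.r * 1e6, "c_nM": res.profile * 1e9}
        )
        prof.to_csv(outdir / f"rd_profile_{name}.csv", index=False)
    pd.DataFrame(rows).to_csv(outdir / "rd_conditions.csv", index=False)
    return {r["condition"]: r["ratio"] for r in rows}


def _stage_synth(cfg: dict, seed: int, outdir: Path) -> dict:
    conditions = cfg.get(
        "conditions", {"lit": 3.0, "no_ilid": 1.0}
    )  # condition -> true membrane:lumen ratio
    n = int(cfg.get("n_per_condition", 15))
    written = {}
    rng_seeds = {
        name: stage_seed(seed, f"synth/{name}") for name in conditions
    }
    for name, truth in conditions.items():
        cohort = synthdata.make_vesicle_cohort(
            float(truth), n=n, seed=rng_seeds[name],
            psf_sigma=float(cfg.get("psf_sigma", 1.5)),
        )
        paths = []
        for i, guv in enumerate(cohort):
            p = outdir / f"vesicle_{name}_{i:02d}.tif"
            synthdata.write_image(guv, p)
            paths.append(str(p))
        written[name] = paths
    return written


def _stage_quant(synth_outputs: dict, outdir: Path) -> pd.DataFrame:
    items = []
    for condition, paths in synth_outputs.items():
        for p in paths:
            guv = synthdata.read_image(p)
            ann = imagequant.Annotation.from_truth_dict(guv.truth.to_json_dict())
            items.append((guv.pixels.astype(float), ann, condition, Path(p).name))
    table, errors = imagequant.batch_quantify(items)
    table.to_csv(outdir / "quant.csv", index=False)
    if errors:
        (outdir / "quant_errors.txt").write_text("\n".join(errors))
    return table


def _stage_stats(table: pd.DataFrame, cfg: dict, outdir: Path) -> dict:
    conditions = list(pd.unique(table["condition"]))
    pair = cfg.get("compare", conditions[:2])
    a = table.loc[table["condition"] == pair[0], "ratio"].to_numpy()
    b = table.loc[table["condition"] == pair[1], "ratio"].to_numpy()
    cmp = welch_t(a, b, labels=(str(pair[0]), str(pair[1])))
    out = {
        "groups": list(cmp.group_labels),
        "n": list(cmp.n),
        "means": list(cmp.means),
        "t_statistic": cmp.t_statistic,
        "welch_df": cmp.welch_df,
        "p_two_sided": cmp.p_two_sided,
        "summary": cmp.summary,
    }
    (outdir / "stats.json").write_text(json.dumps(out, indent=1))
    return out


def run(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order; return the report.

    Stages: ``kinetics`` (trace generation + two-stage rate-constant fit),
    ``rdmodel`` (three-condition steady-state table), ``synth`` (vesicle
    image cohorts per condition), ``quant`` (periphery/interface table from
    the synth outputs), ``stats`` (Welch comparison of the first two — or
    configured — conditions).  All artifacts land in ``config.output_dir``;
    the JSON report (also written there) carries the config hash, per-stage
    seeds, and stage summaries.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "stage_seeds": {s: stage_seed(config.seed, s) for s in config.stages},
        "stages": {},
    }
    synth_outputs: Optional[dict] = None
    quant_table: Optional[pd.DataFrame] = None
    for stage in STAGES:  # dependency order
        if stage not in config.stages:
            continue
        cfg = config.params.get(stage, {}) or {}
        seed = stage_seed(config.seed, stage)
        logger.info("stage %s: seed=%d params=%s", stage, seed, cfg)
        try:
            if stage == "kinetics":
                report["stages"]["kinetics"] = _stage_kinetics(cfg, seed, outdir)
            elif stage == "rdmodel":
                report["stages"]["rdmodel"] = _stage_rdmodel(cfg, outdir)
            elif stage == "synth":
                synth_outputs = _stage_synth(cfg, config.seed, outdir)
                report["stages"]["synth"] = {
                    k: len(v) for k, v in synth_outputs.items()
                }
            elif stage == "quant":
                if synth_outputs is None:
                    raise ValueError("quant stage requires the synth stage outputs")
                quant_table = _stage_quant(synth_outputs, outdir)
                report["stages"]["quant"] = {
                    "n_rows": int(len(quant_table)),
                    "by_condition": {
                        str(k): float(v)
                        for k, v in quant_table.groupby("condition")["ratio"]
                        .mean()
                        .items()
                    },
                }
            elif stage == "stats":
                if quant_table is None:
                    raise ValueError("stats stage requires the quant stage outputs")
                report["stages"]["stats"] = _stage_stats(quant_table, cfg, outdir)
        except Exception as exc:
            report["stages"][stage] = {"error": str(exc)}
            (outdir / "report.json").write_text(json.dumps(report, indent=1))
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    (outdir / "report.json").write_text(json.dumps(report, indent=1))
    return report
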