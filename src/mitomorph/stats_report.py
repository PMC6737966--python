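"""Group statistics and machine-readable reports.

Per-group summaries are mean ± s.e.m. (sample standard deviation with the
n−1 denominator, divided by √n) and pairwise comparisons use the unpaired
two-sample t-test.  The default variant is the classic pooled-variance
Student test; Welch's unequal-variance form is available by flag and is the
better choice when group spreads differ strongly (the cortex and DCN
postsynaptic volumes are visibly heavier-tailed than the presynaptic ones).

The test statistic and degrees of freedom are computed from first
principles here; only the t-distribution tail probability comes from SciPy.
No multiple-testing correction is applied by default — comparisons are
reported per pair — but a Bonferroni option exists for the cross-region
family.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import Compartment

__all__ = [
    "GroupStats",
    "PairwiseTest",
    "HistogramConfig",
    "ReportConfig",
    "group_summary",
    "unpaired_t_test",
    "size_histogram",
    "build_report",
    "write_report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupStats:
    """Summary of one group of per-object measurements."""

    label: str
    n: int
    mean: float
    sem: float
    values: tuple[float, ...]

    def to_json_obj(self) -> dict:
        return {
            "label": self.label,
            "n": self.n,
            "mean": self.mean,
            "sem": None if math.isnan(self.sem) else self.sem,
        }


@dataclass(frozen=True)
class PairwiseTest:
    """Unpaired two-sample t-test result."""

    group_a: str
    group_b: str
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    variant: str

    def to_json_obj(self) -> dict:
        return {
            "group_a": self.group_a,
            "group_b": self.group_b,
            "t": self.t_statistic,
            "df": self.degrees_of_freedom,
            "p": self.p_value,
            "variant": self.variant,
        }


def group_summary(values: Sequence[float], label: str = "") -> GroupStats:
    """Exact mean and s.e.m. of a nonempty list of finite measurements.

    ``sem = sd(n−1 denominator) / sqrt(n)``.  For a single observation the
    s.e.m. is undefined and reported as NaN with a warning.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError(f"group {label!r}: no values")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"group {label!r}: non-finite values present")
    n = int(arr.size)
    mean = float(arr.mean())
    if n == 1:
        warnings.warn(f"group {label!r} has n=1; s.e.m. undefined", stacklevel=2)
        sem = float("nan")
    else:
        sem = float(arr.std(ddof=1) / math.sqrt(n))
    return GroupStats(label=label, n=n, mean=mean, sem=sem, values=tuple(arr.tolist()))


def unpaired_t_test(
    a: Sequence[float],
    b: Sequence[float],
    variant: str = "student",
    group_a: str = "a",
    group_b: str = "b",
) -> PairwiseTest:
    """Two-sided unpaired two-sample t-test.

    ``variant="student"``: pooled variance, df = n_a + n_b − 2.
    ``variant="welch"``: unpooled variance with Welch–Satterthwaite df.
    When both groups have zero variance and equal means the statistic is
    0/0; by convention p = 1 is returned (and logged).
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise ValueError(f"need >= 2 observations per group, got {xa.size} and {xb.size}")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    na, nb = xa.size, xb.size
    va, vb = xa.var(ddof=1), xb.var(ddof=1)
    diff = xa.mean() - xb.mean()

    if variant == "student":
        df = na + nb - 2
        pooled = ((na - 1) * va + (nb - 1) * vb) / df
        se = math.sqrt(pooled * (1.0 / na + 1.0 / nb))
    else:
        sa2, sb2 = va / na, vb / nb
        se = math.sqrt(sa2 + sb2)
        if se == 0.0:
            df = na + nb - 2
        else:
            df = (sa2 + sb2) ** 2 / (sa2**2 / (na - 1) + sb2**2 / (nb - 1))

    if se == 0.0:
        if diff == 0.0:
            logger.warning(
                "zero pooled variance with equal means (%s vs %s): p=1 by convention",
                group_a,
                group_b,
            )
            t = 0.0
            p = 1.0
        else:
            t = math.copysign(math.inf, diff)
            p = 0.0
    else:
        t = diff / se
        p = float(2.0 * sps.t.sf(abs(t), df))
    return PairwiseTest(
        group_a=group_a,
        group_b=group_b,
        t_statistic=float(t),
        degrees_of_freedom=float(df),
        p_value=p,
        variant=variant,
    )


@dataclass(frozen=True)
class HistogramConfig:
    """Size-histogram binning.

    Fixed-width bins from ``start`` with ``bin_width`` (µm³) by default;
    ``log=True`` switches to log-spaced bins (for the long-tailed cortex
    and DCN distributions); explicit ``edges`` override everything.
    """

    bin_width: float = 0.05
    start: float = 0.0
    log: bool = False
    n_log_bins: int = 20
    edges: tuple[float, ...] | None = None


def size_histogram(
    values: Sequence[float], config: HistogramConfig = HistogramConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of per-object sizes; returns ``(edges, counts)``.

    Counts always sum to ``len(values)``: the top edge is extended to cover
    the maximum observation.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("no values to histogram")
    if config.edges is not None:
        edges = np.asarray(config.edges, dtype=float)
        if np.any(np.diff(edges) <= 0):
            raise ValueError("histogram edges must be strictly increasing")
        if arr.min() < edges[0] or arr.max() > edges[-1]:
            raise ValueError("explicit edges do not cover the data range")
    elif config.log:
        lo = arr.min()
        if lo <= 0:
            raise ValueError("log binning requires positive values")
        edges = np.geomspace(lo * (1 - 1e-12), arr.max() * (1 + 1e-12), config.n_log_bins + 1)
    else:
        top = arr.max()
        n_bins = max(1, int(np.ceil((top - config.start) / config.bin_width + 1e-9)))
        edges = config.start + config.bin_width * np.arange(n_bins + 1)
        if edges[-1] <= top:
            edges[-1] = np.nextafter(top, np.inf)
    counts, edges = np.histogram(arr, bins=edges)
    return edges, counts


@dataclass(frozen=True)
class ReportConfig:
    """Configuration for :func:`build_report`."""

    test_variant: str = "student"
    metrics: tuple[str, ...] = ("volume_um3", "mci")
    histogram_metric: str = "volume_um3"
    histogram: HistogramConfig = field(default_factory=HistogramConfig)
    bonferroni_cross_region: bool = False

    def to_json_obj(self) -> dict:
        return {
            "test_variant": self.test_variant,
            "metrics": list(self.metrics),
            "histogram_metric": self.histogram_metric,
            "histogram": {
                "bin_width": self.histogram.bin_width,
                "start": self.histogram.start,
                "log": self.histogram.log,
                "n_log_bins": self.histogram.n_log_bins,
                "edges": list(self.histogram.edges) if self.histogram.edges else None,
            },
            "bonferroni_cross_region": self.bonferroni_cross_region,
        }


_COMPARTMENTS = (Compartment.PRESYNAPTIC.value, Compartment.POSTSYNAPTIC.value)


def build_report(
    tables: Mapping[str, pd.DataFrame], config: ReportConfig = ReportConfig()
) -> dict:
    """Build the group-level report from per-region morphometry tables.

    ``tables`` maps region names (e.g. ``"NA"``) to morphometry DataFrames
    with at least ``compartment`` and the configured metric columns.  The
    report contains, per region × compartment, mean ± s.e.m. for every
    metric; within-region presynaptic-vs-postsynaptic tests; cross-region
    same-compartment tests; and per-group size histograms.  The result is a
    pure function of its inputs (no timestamps), so repeated runs are
    byte-identical once serialised with sorted keys.
    """
    if not tables:
        raise ValueError("no region tables provided")
    groups: dict = {}
    values: dict[tuple[str, str, str], np.ndarray] = {}
    for region in sorted(tables):
        frame = tables[region]
        groups[region] = {}
        for comp in _COMPARTMENTS:
            sub = frame[frame["compartment"] == comp]
            if len(sub) == 0:
                continue
            groups[region][comp] = {}
            for metric in config.metrics:
                vals = sub[metric].to_numpy(dtype=float)
                values[(region, comp, metric)] = vals
                gs = group_summary(vals, label=f"{region}-{comp}")
                groups[region][comp][metric] = gs.to_json_obj()

    within: dict = {}
    for region in sorted(tables):
        have = [c for c in _COMPARTMENTS if (region, c, config.metrics[0]) in values]
        if len(have) < 2:
            logger.warning("region %s lacks a compartment; within-region test skipped", region)
            continue
        within[region] = {}
        for metric in config.metrics:
            test = unpaired_t_test(
                values[(region, _COMPARTMENTS[0], metric)],
                values[(region, _COMPARTMENTS[1], metric)],
                variant=config.test_variant,
                group_a=f"{region}-{_COMPARTMENTS[0]}",
                group_b=f"{region}-{_COMPARTMENTS[1]}",
            )
            within[region][metric] = test.to_json_obj()

    cross: dict = {}
    regions = sorted(tables)
    n_pairs = len(regions) * (len(regions) - 1) // 2
    for comp in _COMPARTMENTS:
        cross[comp] = {}
        for metric in config.metrics:
            pair_results = {}
            for i, ra in enumerate(regions):
                for rb in regions[i + 1 :]:
                    ka, kb = (ra, comp, metric), (rb, comp, metric)
                    if ka not in values or kb not in values:
                        continue
                    test = unpaired_t_test(
                        values[ka],
                        values[kb],
                        variant=config.test_variant,
                        group_a=f"{ra}-{comp}",
                        group_b=f"{rb}-{comp}",
                    )
                    obj = test.to_json_obj()
                    if config.bonferroni_cross_region and n_pairs > 0:
                        obj["p_bonferroni"] = min(1.0, obj["p"] * n_pairs)
                    pair_results[f"{ra}_vs_{rb}"] = obj
            if pair_results:
                cross[comp][metric] = pair_results

    histograms: dict = {}
    for region in sorted(tables):
        histograms[region] = {}
        for comp in _COMPARTMENTS:
            key = (region, comp, config.histogram_metric)
            if key not in values:
                continue
            edges, counts = size_histogram(values[key], config.histogram)
            histograms[region][comp] = {
                "metric": config.histogram_metric,
                "edges": [float(e) for e in edges],
                "counts": [int(c) for c in counts],
            }

    return {
        "config": config.to_json_obj(),
        "groups": groups,
        "tests": {"within_region": within, "cross_region": cross},
        "histograms": histograms,
    }


def write_report(
    report: dict,
    outdir: str | Path,
    tables: Mapping[str, pd.DataFrame] | None = None,
    plots: bool = False,
) -> Path:
    """Write ``report.json`` (sorted keys, stable bytes) plus per-group CSVs.

    With ``plots=True`` an SVG mean±s.e.m. dot plot and per-region
    histograms are also written (matplotlib imported lazily).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
    if tables is not None:
        for region, frame in tables.items():
            frame.to_csv(outdir / f"morphometry_{region}.csv", index=False)
    if plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        regions = sorted(report["groups"])
        fig, ax = plt.subplots(figsize=(1.5 * max(4, len(regions) * 2), 4))
        for i, region in enumerate(regions):
            for j, comp in enumerate(_COMPARTMENTS):
                g = report["groups"][region].get(comp, {}).get("volume_um3")
                if g is None:
                    continue
                x = i + (j - 0.5) * 0.3
                ax.errorbar(x, g["mean"], yerr=g["sem"], fmt="o", capsize=3, color=f"C{j}")
        ax.set_xticks(range(len(regions)))
        ax.set_xticklabels(regions)
        ax.set_ylabel("mitochondrial volume (µm³)")
        fig.tight_layout()
        fig.savefig(outdir / "group_means.svg")
        plt.close(fig)
    return outdir / "report.json"
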