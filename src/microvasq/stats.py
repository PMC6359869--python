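"""Cross-modality agreement and comparison statistics.

The study design is paired: each eye is measured once per modality, and
the questions are (i) do the modalities differ systematically, (ii) how
well do they agree, and (iii) how strongly are readouts correlated.
With two within-unit levels, repeated-measures ANOVA reduces exactly to
the paired t-test (F = t^2 on 1 and n-1 degrees of freedom), which is
how :func:`paired_compare` reports both statistics.

Differences are oriented as (a - b); callers declare which modality is
``a``.  All dispersions are sample (n-1) standard deviations, matching
mean +/- SD reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .errors import StatsError


@dataclass
class PairedResult:
    """Two-level repeated-measures comparison of paired readouts."""

    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    statistic: float          # F on (1, n-1) df
    t_statistic: float        # signed paired t; F == t**2
    p_value: float
    n_pairs: int
    degenerate: bool = False  # zero diff variance with nonzero mean diff


@dataclass
class AgreementStats:
    """Bland–Altman limits of agreement for paired measurements."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int


def _paired_arrays(a: Sequence[float], b: Sequence[float], min_n: int) -> Tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.ndim != 1 or b.ndim != 1 or a.shape != b.shape:
        raise StatsError("paired inputs must be equal-length 1-D sequences")
    if a.size < min_n:
        raise StatsError(f"need at least {min_n} pairs, got {a.size}")
    return a, b


def paired_compare(
    a: Sequence[float],
    b: Sequence[float],
    unit_ids: Optional[Sequence[str]] = None,
) -> PairedResult:
    """Two-level within-unit repeated-measures comparison.

    Computes the paired t on the differences ``a - b`` and reports the
    equivalent one-way RM-ANOVA F = t^2; p is two-sided.  Identical
    inputs give statistic 0 and p = 1.  Zero difference variance with a
    nonzero mean difference is degenerate: reported as p = 0 with the
    ``degenerate`` flag set rather than raising.
    """
    a, b = _paired_arrays(a, b, min_n=3)
    if unit_ids is not None and len(unit_ids) != a.size:
        raise StatsError("unit_ids length must match the number of pairs")
    n = int(a.size)
    d = a - b
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    if sd_d == 0.0:
        if mean_d == 0.0:
            t = 0.0
            p = 1.0
            degenerate = False
        else:
            t = math.inf if mean_d > 0 else -math.inf
            p = 0.0
            degenerate = True
    else:
        t = mean_d / (sd_d / math.sqrt(n))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 1))
        degenerate = False
    return PairedResult(
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        statistic=float(t) ** 2 if math.isfinite(t) else math.inf,
        t_statistic=float(t),
        p_value=p,
        n_pairs=n,
        degenerate=degenerate,
    )


def pearson(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Sample Pearson correlation with its two-sided p-value.

    p comes from ``t = r * sqrt((n-2) / (1-r^2))`` on n-2 df.  Constant
    input leaves the correlation undefined and is rejected.
    """
    x, y = _paired_arrays(x, y, min_n=3)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsError("undefined correlation for constant input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def bland_altman(a: Sequence[float], b: Sequence[float]) -> AgreementStats:
    """Bland–Altman 95% limits of agreement for differences ``a - b``.

    LoA = mean difference +/- 1.96 x the sample SD of the differences.
    """
    a, b = _paired_arrays(a, b, min_n=2)
    d = a - b
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    return AgreementStats(
        mean_diff=mean_d,
        sd_diff=sd_d,
        loa_low=mean_d - 1.96 * sd_d,
        loa_high=mean_d + 1.96 * sd_d,
        n=int(d.size),
    )


def summarize(values: Sequence[float]) -> Tuple[float, float]:
    """Sample mean and sample (n-1) standard deviation."""
    v = np.asarray(values, dtype=np.float64)
    if v.ndim != 1 or v.size < 2:
        raise StatsError("summarize needs at least 2 values")
    return float(v.mean()), float(v.std(ddof=1))


def plot_bland_altman(a: Sequence[float], b: Sequence[float], path: str, title: str = "") -> AgreementStats:
    """Bland–Altman plot (means vs differences, three horizontal lines)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    stats = bland_altman(a, b)
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((a + b) / 2.0, a - b, s=18, color="tab:blue")
    ax.axhline(stats.mean_diff, color="k", lw=1.2)
    ax.axhline(stats.loa_low, color="k", lw=1.0, ls="--")
    ax.axhline(stats.loa_high, color="k", lw=1.0, ls="--")
    ax.set_xlabel("mean of paired measurements")
    ax.set_ylabel("difference (a - b)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return stats
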