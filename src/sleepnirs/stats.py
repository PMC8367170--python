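"""Agreement statistics between fingertip and arm oxygen desaturations.

Bland-Altman limits of agreement on the per-event differences
``finger_OD - arm_OD``, one-sample t tests of those differences against
zero, hypopnea detection rates at the clinical >=3% desaturation
criterion, and Spearman rank correlations in severity subgroups defined
by fingertip-OD cut-offs from 2% to 8%.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, ValidationError

__all__ = [
    "BlandAltmanResult",
    "TTestResult",
    "DetectionRate",
    "SweepPoint",
    "bland_altman",
    "bland_altman_differences",
    "one_sample_t",
    "detection_rate",
    "spearman_sweep",
    "build_agreement_report",
    "bland_altman_plot",
]

LOA_MULTIPLIER = 1.96
DEFAULT_CUTOFFS = (2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0)


@dataclass(frozen=True)
class BlandAltmanResult:
    n: int
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ci95_low: float
    ci95_high: float


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class DetectionRate:
    k: int
    n: int
    rate_pct: float


@dataclass(frozen=True)
class SweepPoint:
    cutoff: float
    n: int
    rho: float
    p: float


def bland_altman_differences(differences: Sequence[float]) -> BlandAltmanResult:
    """Bland-Altman statistics from precomputed paired differences.

    Sample SD (n-1 denominator); limits of agreement mean +/- 1.96*SD
    (the conventional normal-quantile multiplier, not the t quantile);
    95% CI of the mean difference via the Student t quantile at n-1 df.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise InsufficientDataError(f"Bland-Altman needs n >= 2 differences, got {d.size}")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    half = LOA_MULTIPLIER * sd
    tq = float(sps.t.ppf(0.975, d.size - 1))
    sem = sd / np.sqrt(d.size)
    return BlandAltmanResult(
        n=int(d.size),
        mean_diff=mean,
        sd_diff=sd,
        loa_low=mean - half,
        loa_high=mean + half,
        ci95_low=mean - tq * sem,
        ci95_high=mean + tq * sem,
    )


def bland_altman(finger_od: Sequence[float], arm_od: Sequence[float]) -> BlandAltmanResult:
    """Bland-Altman agreement of paired ODs, differences taken as finger - arm."""
    f = np.asarray(finger_od, dtype=float)
    a = np.asarray(arm_od, dtype=float)
    if f.shape != a.shape:
        raise ValidationError("finger and arm OD arrays must have matching shapes")
    return bland_altman_differences(f - a)


def one_sample_t(differences: Sequence[float]) -> TTestResult:
    """Two-sided one-sample t test of the mean difference against zero."""
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise InsufficientDataError(f"t test needs n >= 2, got {d.size}")
    sd = float(d.std(ddof=1))
    if sd == 0:
        raise InsufficientDataError("degenerate t test: zero standard deviation")
    n = d.size
    t = float(d.mean() / (sd / np.sqrt(n)))
    df = n - 1
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TTestResult(t=t, df=df, p=p)


def detection_rate(
    ods: Sequence[float], threshold: float = 3.0, inclusive: bool = True
) -> DetectionRate:
    """Fraction of events whose OD meets the detection criterion (default >= 3%)."""
    x = np.asarray(ods, dtype=float)
    if x.size == 0:
        raise InsufficientDataError("detection rate undefined on an empty list")
    k = int((x >= threshold).sum() if inclusive else (x > threshold).sum())
    return DetectionRate(k=k, n=int(x.size), rate_pct=100.0 * k / x.size)


def spearman_sweep(
    finger_od: Sequence[float],
    arm_od: Sequence[float],
    cutoffs: Iterable[float] = DEFAULT_CUTOFFS,
) -> List[SweepPoint]:
    """Spearman rho between the channels in subgroups with finger_OD >= cutoff.

    Average-rank tie handling (scipy default).  Subgroups with fewer than
    3 pairs, or with a constant coordinate, are reported with rho and p
    undefined (NaN) rather than raising.
    """
    f = np.asarray(finger_od, dtype=float)
    a = np.asarray(arm_od, dtype=float)
    out: List[SweepPoint] = []
    for c in cutoffs:
        sel = f >= c
        n = int(sel.sum())
        if n < 3 or np.unique(f[sel]).size < 2 or np.unique(a[sel]).size < 2:
            out.append(SweepPoint(cutoff=float(c), n=n, rho=float("nan"), p=float("nan")))
            continue
        rho, p = sps.spearmanr(f[sel], a[sel])
        out.append(SweepPoint(cutoff=float(c), n=n, rho=float(rho), p=float(p)))
    return out


def _condition_stats(
    finger: np.ndarray,
    arm: np.ndarray,
    threshold: float,
    cutoffs: Sequence[float],
) -> Dict:
    ba = bland_altman(finger, arm)
    tt = one_sample_t(finger - arm)
    det = detection_rate(arm, threshold)
    return {
        "n_events": ba.n,
        "mean_diff_pct": ba.mean_diff,
        "sd_diff_pct": ba.sd_diff,
        "ci95_mean_pct": [ba.ci95_low, ba.ci95_high],
        "loa_pct": [ba.loa_low, ba.loa_high],
        "t_stat": tt.t,
        "df": tt.df,
        "p_value": tt.p,
        "detection_rate": {"k": det.k, "n": det.n, "rate_pct": det.rate_pct},
        "spearman_sweep": [asdict(pt) for pt in spearman_sweep(finger, arm, cutoffs)],
    }


def build_agreement_report(
    event_table: pd.DataFrame,
    threshold: float = 3.0,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
) -> Dict:
    """Full agreement report from a per-event OD table.

    Excluded events are dropped from every statistic but counted in the
    ledger.  Conditions reported: ``baseline``, every individual CPAP
    pressure step, the pooled ``cpap`` group, and ``all``; each with both
    the raw and the baseline-normalized arm OD.
    """
    excluded = event_table[event_table["excluded"]] if "excluded" in event_table else event_table.iloc[0:0]
    kept = event_table[~event_table["excluded"]] if "excluded" in event_table else event_table

    groups: Dict[str, pd.DataFrame] = {}
    if (kept["condition"] == "baseline").any():
        groups["baseline"] = kept[kept["condition"] == "baseline"]
    cpap = kept[kept["condition"].str.startswith("cpap")]
    if len(cpap):
        groups["cpap"] = cpap
        for label in sorted(cpap["condition"].unique()):
            if label != "cpap":
                groups[label] = cpap[cpap["condition"] == label]
    groups["all"] = kept

    conditions: Dict[str, Dict] = {}
    for label, g in groups.items():
        if len(g) < 2:
            conditions[label] = {"n_events": int(len(g)), "insufficient_data": True}
            continue
        f = g["finger_od"].to_numpy()
        conditions[label] = {
            "raw": _condition_stats(f, g["arm_od"].to_numpy(), threshold, cutoffs),
            "normalized": _condition_stats(f, g["arm_od_norm"].to_numpy(), threshold, cutoffs),
        }

    return {
        "n_events_total": int(len(event_table)),
        "n_excluded": int(len(excluded)),
        "n_analyzed": int(len(kept)),
        "excluded_event_ids": excluded["event_id"].tolist() if len(excluded) else [],
        "conditions": conditions,
    }


def bland_altman_plot(
    finger_od: Sequence[float],
    arm_od: Sequence[float],
    path: Optional[str] = None,
    title: str = "",
):
    """Bland-Altman scatter (mean vs difference) with LoA lines and a marginal histogram."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    f = np.asarray(finger_od, dtype=float)
    a = np.asarray(arm_od, dtype=float)
    ba = bland_altman(f, a)
    d = f - a
    fig, (ax, axh) = plt.subplots(
        1, 2, figsize=(8, 4), gridspec_kw={"width_ratios": [4, 1]}, sharey=True
    )
    ax.scatter((f + a) / 2, d, s=8, alpha=0.4)
    for y, style in ((ba.mean_diff, "-"), (ba.loa_low, ":"), (ba.loa_high, ":")):
        ax.axhline(y, linestyle=style, color="k")
    ax.set_xlabel("mean of finger_OD and arm_OD (%)")
    ax.set_ylabel("finger_OD − arm_OD (%)")
    if title:
        ax.set_title(title)
    axh.hist(d, bins=30, orientation="horizontal", color="gray")
    axh.set_xlabel("count")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
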