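"""Event-timing statistics relative to ROSC.

Builds a subjects x event-types table of "seconds before ROSC", reports
mean +/- SE descriptives, screens normality with the Shapiro-Wilk test
(Royston's AS R94 approximation, implemented here and cross-checked against
scipy in the test suite) and runs uncorrected pairwise Fisher's LSD
comparisons on a one-way ANOVA pooled error term.  A paired
(repeated-measures) error-term variant is available since each subject
typically contributes every event type.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .events import EventSet

__all__ = [
    "EVENT_TYPES",
    "ComparisonResult",
    "build_timing_table",
    "describe",
    "shapiro_wilk",
    "fisher_lsd",
    "compare_event_timings",
]

logger = logging.getLogger(__name__)

#: canonical event-type columns of the timing table, in reporting order
EVENT_TYPES = (
    "tail_piva_peak",
    "femoral_piva_peak",
    "central_piva_peak",
    "etco2_rise",
)


def build_timing_table(
    event_sets: Mapping[str, EventSet] | Sequence[EventSet],
) -> pd.DataFrame:
    """Subjects x event-types table of ``rosc_time - event_time`` (s).

    Positive entries mean the event preceded ROSC.  Events occurring after
    ROSC give negative entries, which are retained and flagged in the log;
    absent events give NaN cells.
    """
    if not isinstance(event_sets, Mapping):
        event_sets = {f"subject_{i:02d}": es for i, es in enumerate(event_sets)}
    rows = {}
    for subject, es in event_sets.items():
        row: dict[str, float] = {}
        for channel, t in es.piva_peak_time.items():
            site = channel.replace("_venous", "")
            row[f"{site}_piva_peak"] = es.rosc_time - t
        if es.etco2_rise_time is not None:
            row["etco2_rise"] = es.rosc_time - es.etco2_rise_time
        else:
            logger.info("subject %s: no etCO2 criterion met; cell left missing", subject)
        for name, v in row.items():
            if v < 0:
                logger.warning(
                    "subject %s: event %s occurred %.3g s after ROSC", subject, name, -v
                )
        rows[subject] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    # keep canonical ordering for known event types, extras appended
    cols = [c for c in EVENT_TYPES if c in table.columns] + [
        c for c in table.columns if c not in EVENT_TYPES
    ]
    return table.reindex(columns=cols)


def describe(values) -> tuple[float, float, int]:
    """Mean, standard error (sd with n-1 denominator over sqrt(n)) and n.

    NaNs are dropped; ``n = 1`` gives ``se = 0``; ``n = 0`` raises.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    n = len(x)
    if n == 0:
        raise ValueError("describe requires at least one non-missing value")
    mean = float(x.mean())
    se = 0.0 if n == 1 else float(x.std(ddof=1) / math.sqrt(n))
    return mean, se, n


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p-value (Royston 1995 approximation, AS R94).

    Valid for 3 <= n <= 5000.  Raises on shorter samples and on
    zero-variance input, where W is undefined.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n < 3:
        raise ValueError(f"Shapiro-Wilk requires n >= 3, got n={n}")
    if n > 5000:
        raise ValueError(f"Shapiro-Wilk approximation invalid for n > 5000 (n={n})")
    if x[-1] - x[0] == 0:
        raise ValueError("Shapiro-Wilk undefined for zero-variance (constant) data")

    # Blom-type expected normal order statistics and normalized weights
    m = sps.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    mm = float(m @ m)
    c = m / math.sqrt(mm)
    rsn = 1.0 / math.sqrt(n)
    a = np.empty(n)
    if n == 3:
        a[0], a[1], a[2] = -math.sqrt(0.5), 0.0, math.sqrt(0.5)
    else:
        a_n = (
            -2.706056 * rsn**5
            + 4.434685 * rsn**4
            - 2.071190 * rsn**3
            - 0.147981 * rsn**2
            + 0.221157 * rsn
            + c[-1]
        )
        if n <= 5:
            phi = (mm - 2.0 * m[-1] ** 2) / (1.0 - 2.0 * a_n**2)
            a[1:-1] = m[1:-1] / math.sqrt(phi)
            a[-1], a[0] = a_n, -a_n
        else:
            a_n1 = (
                -3.582633 * rsn**5
                + 5.682633 * rsn**4
                - 1.752461 * rsn**3
                - 0.293762 * rsn**2
                + 0.042981 * rsn
                + c[-2]
            )
            phi = (mm - 2.0 * m[-1] ** 2 - 2.0 * m[-2] ** 2) / (
                1.0 - 2.0 * a_n**2 - 2.0 * a_n1**2
            )
            a[2:-2] = m[2:-2] / math.sqrt(phi)
            a[-1], a[-2] = a_n, a_n1
            a[0], a[1] = -a_n, -a_n1

    ss = float(np.sum((x - x.mean()) ** 2))
    w = float((a @ x) ** 2 / ss)
    w = min(w, 1.0)

    if n == 3:
        p = (6.0 / math.pi) * (math.asin(math.sqrt(w)) - math.asin(math.sqrt(0.75)))
        p = min(max(p, 0.0), 1.0)
    elif n <= 11:
        g = -2.273 + 0.459 * n
        mu = 0.5440 - 0.39978 * n + 0.025054 * n**2 - 0.0006714 * n**3
        sigma = math.exp(1.3822 - 0.77857 * n + 0.062767 * n**2 - 0.0020322 * n**3)
        z = (-math.log(g - math.log1p(-w)) - mu) / sigma
        p = float(sps.norm.sf(z))
    else:
        u = math.log(n)
        mu = -1.5861 - 0.31082 * u - 0.083751 * u**2 + 0.0038915 * u**3
        sigma = math.exp(-0.4803 - 0.082676 * u + 0.0030302 * u**2)
        z = (math.log1p(-w) - mu) / sigma
        p = float(sps.norm.sf(z))
    return w, p


@dataclass
class ComparisonResult:
    """Descriptives, normality screens and uncorrected pairwise LSD tests."""

    group_stats: dict[str, dict]  # name -> {mean, se, n}
    shapiro: dict[str, dict]  # name -> {W, p} (absent for n < 3)
    pairwise_p: pd.DataFrame  # symmetric, NaN diagonal
    pairwise_t: pd.DataFrame
    df_error: int
    mse: float
    alpha: float = 0.05
    paired: bool = False
    significant: list[tuple[str, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        def _frame(df: pd.DataFrame) -> dict:
            return {
                r: {c: (None if pd.isna(v) else float(v)) for c, v in row.items()}
                for r, row in df.iterrows()
            }

        return {
            "group_stats": self.group_stats,
            "shapiro_wilk": self.shapiro,
            "pairwise_p": _frame(self.pairwise_p),
            "pairwise_t": _frame(self.pairwise_t),
            "df_error": self.df_error,
            "mse": self.mse,
            "alpha": self.alpha,
            "paired": self.paired,
            "significant_pairs": [list(p) for p in self.significant],
        }


def _lsd_unpaired(groups: dict[str, np.ndarray]) -> tuple[float, int]:
    """Pooled one-way ANOVA error mean square and its df."""
    n_total = sum(len(g) for g in groups.values())
    k = len(groups)
    ssw = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups.values())
    df = n_total - k
    return ssw / df, df


def fisher_lsd(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    paired: bool = False,
) -> ComparisonResult:
    """Uncorrected pairwise Fisher's LSD comparisons.

    Unpaired (default): one-way ANOVA pooled error mean square, pairwise
    ``t = (mean_i - mean_j) / sqrt(MSE (1/n_i + 1/n_j))`` with
    ``df = N - k``, two-sided p-values, no multiplicity correction.

    ``paired=True`` uses the repeated-measures (subject x condition
    interaction) error term; it requires complete rectangular data — every
    group the same length with positionally matched subjects.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    clean: dict[str, np.ndarray] = {}
    for name, vals in groups.items():
        x = np.asarray(vals, dtype=float)
        x = x[~np.isnan(x)]
        if len(x) >= 1:
            clean[name] = x
    if len(clean) < 2:
        raise ValueError("Fisher's LSD requires at least 2 non-empty groups")
    for name, x in clean.items():
        if len(x) < 2:
            raise ValueError(f"group {name!r} has n={len(x)} < 2")

    names = list(clean)
    if paired:
        lengths = {len(x) for x in clean.values()}
        if len(lengths) != 1:
            raise ValueError(
                "paired LSD requires equal-length, complete groups; got sizes "
                f"{sorted(len(x) for x in clean.values())}"
            )
        n = lengths.pop()
        k = len(names)
        mat = np.column_stack([clean[m] for m in names])  # subjects x groups
        resid = (
            mat
            - mat.mean(axis=1, keepdims=True)
            - mat.mean(axis=0, keepdims=True)
            + mat.mean()
        )
        df = (n - 1) * (k - 1)
        mse = float(np.sum(resid**2) / df)
    else:
        mse, df = _lsd_unpaired(clean)

    if mse <= 0:
        raise ValueError(
            "pooled error variance is zero; LSD t statistics are undefined"
        )

    t_mat = pd.DataFrame(np.nan, index=names, columns=names)
    p_mat = pd.DataFrame(np.nan, index=names, columns=names)
    significant: list[tuple[str, str]] = []
    for i, gi in enumerate(names):
        for j in range(i + 1, len(names)):
            gj = names[j]
            xi, xj = clean[gi], clean[gj]
            if paired:
                se = math.sqrt(2.0 * mse / len(xi))
            else:
                se = math.sqrt(mse * (1.0 / len(xi) + 1.0 / len(xj)))
            t = (xi.mean() - xj.mean()) / se
            p = 2.0 * float(sps.t.sf(abs(t), df))
            t_mat.loc[gi, gj] = t_mat.loc[gj, gi] = t
            p_mat.loc[gi, gj] = p_mat.loc[gj, gi] = p
            if p < alpha:
                significant.append((gi, gj))

    group_stats = {}
    shapiro: dict[str, dict] = {}
    for name, x in clean.items():
        mean, se, n = describe(x)
        group_stats[name] = {"mean": mean, "se": se, "n": n}
        if len(x) >= 3 and x.max() > x.min():
            w, p = shapiro_wilk(x)
            shapiro[name] = {"W": w, "p": p}

    return ComparisonResult(
        group_stats=group_stats,
        shapiro=shapiro,
        pairwise_p=p_mat,
        pairwise_t=t_mat,
        df_error=df,
        mse=mse,
        alpha=alpha,
        paired=paired,
        significant=significant,
    )


def compare_event_timings(
    timing_table: pd.DataFrame,
    alpha: float = 0.05,
    paired: bool = False,
) -> ComparisonResult:
    """Run :func:`fisher_lsd` over the columns of a timing table.

    With ``paired=True`` only subjects with all event types present are used
    (complete-case); unpaired mode uses all available values per column.
    """
    table = timing_table
    if paired:
        table = table.dropna(axis=0, how="any")
    groups = {c: table[c].dropna().to_numpy() for c in table.columns}
    groups = {c: v for c, v in groups.items() if len(v) > 0}
    return fisher_lsd(groups, alpha=alpha, paired=paired)
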