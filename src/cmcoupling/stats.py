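"""Statistical inference on coupling estimates.

Three layers: nonparametric significance of a single TE value against a
surrogate null (circular time shift of the source), one-way repeated-measures
ANOVA for condition comparisons across subjects, and Pearson correlation for
amplitude-coupling relations. The significance level used for reported
decisions is fixed at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .infotheory import CouplingEstimate
from .protocols import EmbeddingSpec
from .transfer_entropy import _u_to_samples, te_ksg

__all__ = [
    "ALPHA",
    "surrogate_test",
    "AnovaResult",
    "rm_anova",
    "PearsonResult",
    "pearson_corr",
    "summarize_conditions",
    "holm_correction",
]

ALPHA = 0.05


def surrogate_test(
    source: np.ndarray,
    target: np.ndarray,
    spec: EmbeddingSpec,
    n_surrogates: int = 19,
    method: str = "circular_shift",
    fs: float = 2000.0,
    seed: int = 0,
    source_spec: EmbeddingSpec | None = None,
) -> CouplingEstimate:
    """Test a TE estimate against a surrogate null distribution.

    ``circular_shift`` surrogates rotate the source by a uniform-random shift
    of at least ``theiler + u`` samples (and at most ``n`` minus that), which
    destroys the source-target alignment while preserving both marginal
    dynamics; ``shuffle`` surrogates permute the source samples outright.
    The p-value is the rank-based exceedance probability
    ``(1 + #{TE_surr >= TE_obs}) / (1 + n_surrogates)``.
    """
    if n_surrogates < 19:
        raise ValueError(
            f"need at least 19 surrogates for a test at alpha=0.05, "
            f"got {n_surrogates}"
        )
    if method not in ("circular_shift", "shuffle"):
        raise ValueError(f"unknown surrogate method {method!r}")
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    n = source.size
    obs = te_ksg(source, target, spec, fs=fs, source_spec=source_spec)
    rng = np.random.default_rng(seed)
    min_shift = max(spec.theiler, 1) + _u_to_samples(spec.u, fs)
    if method == "circular_shift" and n - min_shift <= min_shift:
        raise ValueError(
            f"series of length {n} too short for circular shifts of at "
            f"least {min_shift} samples"
        )
    surr_vals = np.empty(n_surrogates)
    for i in range(n_surrogates):
        if method == "circular_shift":
            shift = int(rng.integers(min_shift, n - min_shift))
            surr = np.roll(source, shift)
        else:
            surr = rng.permutation(source)
        surr_vals[i] = te_ksg(
            surr, target, spec, fs=fs, source_spec=source_spec
        ).value
    obs.attach_surrogates(surr_vals)
    obs.params["surrogate_method"] = method
    obs.params["surrogate_seed"] = seed
    return obs


@dataclass(frozen=True)
class AnovaResult:
    """One-way repeated-measures ANOVA table."""

    F: float
    df_condition: int
    df_error: int
    p_value: float
    ss_condition: float
    ss_subject: float
    ss_error: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def rm_anova(
    table: pd.DataFrame,
    value: str = "value",
    subject: str = "subject",
    condition: str = "condition",
) -> AnovaResult:
    """One-way within-subjects (repeated measures) ANOVA.

    ``table`` is long-format with one column each for subject, condition and
    the measured value; multiple rows per (subject, condition) cell are
    averaged first (per-trial estimates collapse to a cell mean). The design
    must be balanced: every subject must have every condition. The classical
    decomposition is used: F = MS_condition / MS_error with degrees of
    freedom (c - 1, (c - 1)(s - 1)); no sphericity correction is applied.
    """
    for col in (value, subject, condition):
        if col not in table.columns:
            raise ValueError(f"table is missing required column {col!r}")
    cells = table.pivot_table(
        index=subject, columns=condition, values=value, aggfunc="mean"
    )
    if cells.isna().any().any():
        missing = [
            f"(subject={i}, condition={c})"
            for i in cells.index for c in cells.columns
            if pd.isna(cells.loc[i, c])
        ]
        raise ValueError(
            "unbalanced design; missing cells: " + ", ".join(missing)
        )
    s, c = cells.shape
    if s < 2:
        raise ValueError(f"repeated-measures ANOVA needs >= 2 subjects, got {s}")
    if c < 2:
        raise ValueError(f"needs >= 2 conditions, got {c}")
    x = cells.to_numpy(dtype=float)
    gm = x.mean()
    ss_cond = s * float(((x.mean(axis=0) - gm) ** 2).sum())
    ss_subj = c * float(((x.mean(axis=1) - gm) ** 2).sum())
    ss_total = float(((x - gm) ** 2).sum())
    ss_err = ss_total - ss_cond - ss_subj
    df_c = c - 1
    df_e = (c - 1) * (s - 1)
    ms_err = ss_err / df_e
    if ms_err <= 0:
        if ss_cond <= 1e-300:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = np.inf, 0.0
    else:
        f_stat = (ss_cond / df_c) / ms_err
        p = float(sps.f.sf(f_stat, df_c, df_e))
    return AnovaResult(
        F=float(f_stat), df_condition=df_c, df_error=df_e, p_value=p,
        ss_condition=ss_cond, ss_subject=ss_subj, ss_error=max(ss_err, 0.0),
    )


@dataclass(frozen=True)
class PearsonResult:
    rho: float
    rho_squared: float
    p_value: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def pearson_corr(x: np.ndarray, y: np.ndarray) -> PearsonResult:
    """Pearson correlation with two-sided t-test p-value.

    Reports rho, rho^2 (proportion of variance shared) and the p-value from
    t = r * sqrt((n - 2) / (1 - r^2)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 paired values, got {x.size}")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return PearsonResult(
        rho=float(r), rho_squared=float(r * r), p_value=float(p), n=x.size
    )


def summarize_conditions(
    table: pd.DataFrame,
    value: str = "value",
    condition: str = "condition",
) -> pd.DataFrame:
    """Per-condition mean +/- sample SD (ddof=1) and n.

    Conditions with a single observation get SD 0 and ``degenerate=True``.
    """
    if table.empty:
        raise ValueError("empty estimates table")
    rows = []
    for cond, grp in table.groupby(condition, sort=True):
        vals = grp[value].to_numpy(dtype=float)
        if vals.size == 0:
            raise ValueError(f"condition {cond!r} has no values")
        degenerate = vals.size == 1
        rows.append({
            condition: cond,
            "mean": float(vals.mean()),
            "sd": 0.0 if degenerate else float(vals.std(ddof=1)),
            "n": int(vals.size),
            "degenerate": degenerate,
        })
    return pd.DataFrame(rows).set_index(condition)


def holm_correction(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (off by default in all reports)."""
    p = np.asarray(list(p_values), dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj
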