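"""Test-retest reliability: intraclass correlation and change-change coupling.

The default ICC form is ICC(2,1): two-way random effects, absolute
agreement, single measure — both sessions are treated as random draws from
a population of measurement occasions, so systematic session shifts count
against agreement.  ICC(3,1) (consistency) is available for sensitivity.
Confidence intervals are percentile bootstrap over subjects; the p-value
is the one-sided F-test of ICC > 0 from the between/within mean squares.

A measure is read as trait-like when its ICC is high, and state-like when
its ICC is low while the session-to-session *changes* in the measure and
in its neural correlate move together (Pearson correlation of paired
differences).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    p: float
    form: str
    n_subjects: int
    n_boot: int
    seed: int


def _mean_squares(d: np.ndarray):
    """Row/column/error mean squares of an (n, k) two-way layout.

    Works on a batch: ``d`` may be (B, n, k); returns arrays over B.
    """
    squeeze = d.ndim == 2
    if squeeze:
        d = d[None]
    B, n, k = d.shape
    gm = d.mean(axis=(1, 2))
    rm = d.mean(axis=2)
    cm = d.mean(axis=1)
    msr = k * ((rm - gm[:, None]) ** 2).sum(axis=1) / (n - 1)
    msc = n * ((cm - gm[:, None]) ** 2).sum(axis=1) / (k - 1)
    sse = ((d - rm[:, :, None] - cm[:, None, :] + gm[:, None, None]) ** 2
           ).sum(axis=(1, 2))
    mse = sse / ((n - 1) * (k - 1))
    if squeeze:
        return msr[0], msc[0], mse[0]
    return msr, msc, mse


def _icc_from_ms(msr, msc, mse, n, k, form):
    with np.errstate(divide="ignore", invalid="ignore"):
        if form == "icc2_1":
            denom = msr + (k - 1) * mse + k * (msc - mse) / n
        elif form == "icc3_1":
            denom = msr + (k - 1) * mse
        else:
            raise ValueError(f"unknown ICC form {form!r}")
        out = np.where(denom != 0, (msr - mse) / np.where(denom != 0, denom, 1.0),
                       0.0)
    return out


def icc(session1, session2, n_boot: int = 5000, seed: int = 0,
        form: str = "icc2_1") -> ICCResult:
    """Intraclass correlation between two paired sessions.

    Parameters
    ----------
    session1, session2
        Paired measurements, one value per subject, no missing pairs.
    n_boot
        Percentile-bootstrap resamples (over subjects) for the CI.
    form
        ``"icc2_1"`` (default, absolute agreement) or ``"icc3_1"``.
    """
    s1 = np.asarray(session1, dtype=float)
    s2 = np.asarray(session2, dtype=float)
    if s1.shape != s2.shape or s1.ndim != 1:
        raise ValueError("sessions must be paired 1-D arrays")
    if np.isnan(s1).any() or np.isnan(s2).any():
        raise ValueError("missing pairs are not allowed; drop them upstream")
    n = s1.size
    if n < 5:
        raise ValueError(f"need >= 5 subjects, got {n}")
    d = np.column_stack([s1, s2])
    k = 2
    msr, msc, mse = _mean_squares(d)
    if np.isclose(d.mean(axis=1).var(), 0.0):
        logger.warning("zero between-subject variance; ICC reported as 0")
        value = 0.0
    else:
        value = float(_icc_from_ms(msr, msc, mse, n, k, form))

    # one-sided F-test of ICC > 0
    if mse > 0:
        f = msr / mse
        p = float(stats.f.sf(f, n - 1, (n - 1) * (k - 1)))
    else:
        p = 0.0 if msr > 0 else 1.0
    p = min(max(p, np.finfo(float).tiny), 1.0)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    msr_b, msc_b, mse_b = _mean_squares(d[idx])
    boot = _icc_from_ms(msr_b, msc_b, mse_b, n, k, form)
    ci_low, ci_high = np.nanpercentile(boot, [2.5, 97.5])
    return ICCResult(icc=value, ci_low=float(ci_low), ci_high=float(ci_high),
                     p=p, form=form, n_subjects=n, n_boot=n_boot, seed=seed)


def change_correlation(delta_scores, delta_connectivity):
    """Pearson correlation between paired session-to-session changes.

    Returns ``(r, p)`` with the two-sided t-based p-value.
    """
    ds = np.asarray(delta_scores, dtype=float)
    dc = np.asarray(delta_connectivity, dtype=float)
    if ds.shape != dc.shape or ds.ndim != 1:
        raise ValueError("paired difference vectors required")
    if ds.size < 5:
        raise ValueError("need >= 5 subjects")
    if ds.std() == 0 or dc.std() == 0:
        raise ValueError("zero-variance change vector")
    r, p = stats.pearsonr(ds, dc)
    return float(r), float(p)
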