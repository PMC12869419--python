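"""Double-blind reader-study statistics: trials, agreement, Cohen's kappa.

The study design presents each case twice — once as the real
(contrast-derived) perfusion set and once as the synthesized set — in
two separate trials with shuffled pseudo-IDs, so no reader sees both
arms of a case in one sitting.  Agreement between the two arms is then
summarized per question with a contingency table, percent agreement
(Wilson 95% CI), and Cohen's kappa (asymptotic delta-method CI, with a
seeded bootstrap alternative).  Degenerate tables in which the expected
chance agreement is 1 (both arms constant) are assigned kappa = 0: with
no response variability the statistic carries no chance-corrected
information.

A Monte-Carlo power routine checks how often a true underlying kappa
would be detected at a given sample size: paired categorical responses
are simulated from common marginals with the diagonal inflated to
calibrate the target kappa, and the fraction of replicates rejecting
the kappa = 0 null (Wald test) estimates the power.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "RatingTable",
    "AgreementResult",
    "build_trials",
    "contingency",
    "percent_agreement",
    "cohens_kappa",
    "kappa_power",
]


@dataclass
class RatingTable:
    """Long-format categorical responses from the two rating arms."""

    frame: pd.DataFrame  # columns: case_id, rater, question, arm, category

    REQUIRED = ("case_id", "rater", "question", "arm", "category")

    def __post_init__(self):
        missing = set(self.REQUIRED) - set(self.frame.columns)
        if missing:
            raise ValueError(f"rating table missing columns: {sorted(missing)}")
        dup = self.frame.duplicated(subset=["case_id", "rater", "question", "arm"])
        if dup.any():
            raise ValueError("duplicate (case, rater, question, arm) responses")

    def paired(self, question) -> tuple:
        """Return aligned (real, synthetic) response arrays for a question."""
        q = self.frame[self.frame["question"] == question]
        piv = q.pivot_table(index=["case_id", "rater"], columns="arm",
                            values="category", aggfunc="first")
        piv = piv.dropna()
        return piv["real"].to_numpy(), piv["synthetic"].to_numpy()

    @classmethod
    def from_csv(cls, path) -> "RatingTable":
        return cls(pd.read_csv(path))


@dataclass
class AgreementResult:
    """Agreement summary for one question."""

    n: int
    percent_agreement: float
    percent_ci: tuple
    kappa: float
    kappa_ci: tuple
    matrix: np.ndarray
    categories: tuple
    marginals_a: np.ndarray = field(default=None)
    marginals_b: np.ndarray = field(default=None)


def build_trials(case_ids, seed: int = 0) -> tuple:
    """Randomize cases into two blinded trial rosters.

    Each trial receives exactly one arm (real or synthetic) per case;
    the two arms of a case always land in different trials.  Orders are
    shuffled independently and pseudo-IDs assigned per trial.  Returns
    ``(trial_a, trial_b, unblinding)`` where the rosters are DataFrames
    with columns (pseudo_id, arm) and ``unblinding`` maps pseudo-IDs
    back to (case_id, arm).
    """
    case_ids = list(case_ids)
    if len(set(case_ids)) != len(case_ids):
        raise ValueError("duplicate case ids")
    rng = np.random.default_rng(seed)
    arm_a = rng.integers(0, 2, size=len(case_ids))  # 1: real goes to trial A
    rosters = {"A": [], "B": []}
    for cid, a in zip(case_ids, arm_a):
        rosters["A"].append((cid, "real" if a else "synthetic"))
        rosters["B"].append((cid, "synthetic" if a else "real"))
    out, unblinding = [], {}
    for trial in ("A", "B"):
        entries = rosters[trial]
        order = rng.permutation(len(entries))
        rows = []
        for pos, idx in enumerate(order):
            cid, arm = entries[idx]
            pid = f"{trial}-{pos + 1:03d}"
            rows.append({"pseudo_id": pid, "arm": arm})
            unblinding[pid] = (cid, arm)
        out.append(pd.DataFrame(rows))
    return out[0], out[1], unblinding


def contingency(a, b, categories=None) -> tuple:
    """k x k cross-tabulation of paired responses (rows: arm a).

    Includes categories with zero counts; returns ``(matrix, categories)``.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("response arrays must be paired")
    if categories is None:
        categories = sorted(set(a.tolist()) | set(b.tolist()))
    categories = list(categories)
    index = {c: i for i, c in enumerate(categories)}
    unknown = [v for v in np.concatenate([a, b]) if v not in index]
    if unknown:
        raise ValueError(f"responses outside the codebook: {sorted(set(unknown))}")
    k = len(categories)
    mat = np.zeros((k, k), dtype=int)
    for x, y in zip(a, b):
        mat[index[x], index[y]] += 1
    return mat, tuple(categories)


def percent_agreement(matrix, alpha: float = 0.05) -> tuple:
    """Observed agreement = trace/n, with a Wilson score interval."""
    mat = np.asarray(matrix)
    n = int(mat.sum())
    if n == 0:
        raise ValueError("empty contingency table")
    hits = int(np.trace(mat))
    p = hits / n
    lo, hi = proportion_confint(hits, n, alpha=alpha, method="wilson")
    return p, (float(lo), float(hi))


def _kappa_se(p: np.ndarray, n: int) -> float:
    """Large-sample SE of kappa (Fleiss-Cohen-Everitt delta method)."""
    pr, pc = p.sum(axis=1), p.sum(axis=0)
    po = np.trace(p)
    pe = float(pr @ pc)
    if 1.0 - pe <= 0:
        return 0.0
    k = p.shape[0]
    term1 = sum(
        p[i, i] * ((1 - pe) - (pr[i] + pc[i]) * (1 - po)) ** 2 for i in range(k)
    )
    term2 = (1 - po) ** 2 * sum(
        p[i, j] * (pc[i] + pr[j]) ** 2
        for i in range(k) for j in range(k) if i != j
    )
    term3 = (po * pe - 2 * pe + po) ** 2
    var = (term1 + term2 - term3) / (n * (1 - pe) ** 4)
    return float(np.sqrt(max(var, 0.0)))


def cohens_kappa(matrix, alpha: float = 0.05, ci: str = "asymptotic",
                 n_boot: int = 2000, seed: int = 0) -> tuple:
    """Cohen's kappa with a 95% CI.

    ``ci`` is "asymptotic" (delta-method SE) or "bootstrap" (seeded,
    resampling pairs).  A degenerate table with chance agreement 1
    (both raters constant) returns kappa = 0 with a (0, 0) interval.
    """
    mat = np.asarray(matrix, dtype=float)
    n = int(mat.sum())
    if n == 0:
        raise ValueError("empty contingency table")
    p = mat / n
    po = float(np.trace(p))
    pe = float(p.sum(axis=1) @ p.sum(axis=0))
    if 1.0 - pe <= 1e-12:
        return 0.0, (0.0, 0.0)
    kappa = (po - pe) / (1.0 - pe)
    z = float(-_norm_ppf(alpha / 2.0))
    if ci == "asymptotic":
        se = _kappa_se(p, n)
        lo, hi = kappa - z * se, kappa + z * se
    elif ci == "bootstrap":
        rng = np.random.default_rng(seed)
        k = mat.shape[0]
        pairs = [(i, j) for i in range(k) for j in range(k)]
        probs = p.ravel()
        stats = []
        for _ in range(n_boot):
            counts = rng.multinomial(n, probs).reshape(k, k)
            bp = counts / n
            bpe = float(bp.sum(axis=1) @ bp.sum(axis=0))
            if 1.0 - bpe <= 1e-12:
                stats.append(0.0)
            else:
                stats.append((float(np.trace(bp)) - bpe) / (1.0 - bpe))
        lo, hi = np.quantile(stats, [alpha / 2.0, 1.0 - alpha / 2.0])
    else:
        raise ValueError(f"unknown CI method: {ci!r}")
    return float(kappa), (float(max(lo, -1.0)), float(min(hi, 1.0)))


def _norm_ppf(q: float) -> float:
    from scipy.stats import norm

    return float(norm.ppf(q))


def analyze_question(table: RatingTable, question, categories=None) -> AgreementResult:
    """Full agreement summary (table, percent, kappa) for one question."""
    a, b = table.paired(question)
    mat, cats = contingency(a, b, categories)
    pa, pa_ci = percent_agreement(mat)
    kap, kap_ci = cohens_kappa(mat)
    return AgreementResult(
        n=int(mat.sum()), percent_agreement=pa, percent_ci=pa_ci,
        kappa=kap, kappa_ci=kap_ci, matrix=mat, categories=cats,
        marginals_a=mat.sum(axis=1), marginals_b=mat.sum(axis=0),
    )


def kappa_power(true_kappa: float, marginals, n: int, alpha: float = 0.05,
                reps: int = 2000, seed: int = 0) -> float:
    """Monte-Carlo power of the Wald test of kappa = 0.

    Paired responses are drawn from the joint distribution
    ``(1 - kappa) * outer(m, m) + kappa * diag(m)`` whose rows and
    columns both follow the common marginal ``m`` and whose Cohen's
    kappa equals ``true_kappa`` exactly.  Each replicate is tested with
    the asymptotic two-sided Wald statistic at level ``alpha``.
    """
    if reps < 1:
        raise ValueError("reps must be positive")
    m = np.asarray(marginals, dtype=float)
    if m.ndim != 1 or m.size < 2 or not np.isclose(m.sum(), 1.0) or (m < 0).any():
        raise ValueError("marginals must be a probability vector over >=2 categories")
    joint = (1.0 - true_kappa) * np.outer(m, m) + true_kappa * np.diag(m)
    if (joint < -1e-12).any():
        raise ValueError("true_kappa incompatible with the marginals")
    joint = np.clip(joint, 0.0, None)
    joint /= joint.sum()
    k = m.size
    rng = np.random.default_rng(seed)
    z = float(-_norm_ppf(alpha / 2.0))
    rejections = 0
    for _ in range(reps):
        counts = rng.multinomial(n, joint.ravel()).reshape(k, k)
        p = counts / n
        pe = float(p.sum(axis=1) @ p.sum(axis=0))
        if 1.0 - pe <= 1e-12:
            continue
        kap = (float(np.trace(p)) - pe) / (1.0 - pe)
        se = _kappa_se(p, n)
        if se > 0 and abs(kap) / se > z:
            rejections += 1
    return rejections / reps
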