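"""Two-class linear discriminant analysis in (solidity, convexity) space,
confusion-matrix statistics, and group comparison.

The LDA is the textbook Gaussian discriminant with pooled covariance and
equal priors.  The decision boundary is reported as the line y = a*x + b
(x = solidity, y = convexity); the group on the higher-convexity side of
the line is the ``positive_label`` (the wild-type convention), which is
overridable.  Points exactly on the boundary classify as positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

_SYM_TOL = 1e-12


@dataclass
class DiscriminantLine:
    """Decision boundary y = a*x + b; ``positive_label`` wins for y > a*x + b."""

    a: float
    b: float
    positive_label: str
    negative_label: str

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a) and np.isfinite(self.b)):
            raise ValueError(f"line coefficients must be finite, got a={self.a}, b={self.b}")


@dataclass
class LdaModel:
    """Fitted two-class LDA: per-class means, pooled covariance, equal priors."""

    labels: tuple[str, str]
    means: dict[str, np.ndarray]
    pooled_cov: np.ndarray
    weights: np.ndarray      # w such that the discriminant is w.(x,y) + c
    bias: float              # c; positive side = labels[1]

    def __post_init__(self) -> None:
        cov = np.asarray(self.pooled_cov, dtype=float)
        if cov.shape != (2, 2) or np.abs(cov - cov.T).max() > _SYM_TOL * max(1.0, np.abs(cov).max()):
            raise ValueError("pooled covariance must be a symmetric 2x2 matrix")
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise ValueError("pooled covariance must be positive-definite")
        self.pooled_cov = cov


@dataclass
class ConfusionMatrix:
    """counts[i][j] = samples with true label ``labels[i]`` predicted ``labels[j]``."""

    labels: tuple[str, str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (2, 2) or (counts < 0).any():
            raise ValueError("counts must be a 2x2 array of nonnegative integers")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.equal(np.mod(counts, 1), 0).all():
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        self.counts = counts

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class TestResult:
    """Two-sample test outcome."""

    statistic: float
    df: float
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


# ---------------------------------------------------------------------------
# LDA


def fit_lda(samples: Sequence[Sequence[float]], labels: Sequence[str]) -> LdaModel:
    """Fit two-class Fisher/Gaussian LDA with pooled covariance, equal priors.

    ``samples`` are (x, y) = (solidity, convexity) pairs.  Requires two
    classes with >= 2 samples each and an invertible pooled covariance.
    """
    X = np.asarray(samples, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[1] != 2 or len(X) != len(y):
        raise ValueError("samples must be (n, 2) with one label per row")
    classes = sorted(set(map(str, y)))
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {classes}")
    groups = [X[y == c] for c in classes]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each class needs >= 2 samples")
    means = {c: g.mean(axis=0) for c, g in zip(classes, groups)}
    n0, n1 = len(groups[0]), len(groups[1])
    scatter = sum(np.cov(g, rowvar=False) * (len(g) - 1) for g in groups)
    pooled = scatter / (n0 + n1 - 2)
    if np.linalg.eigvalsh(pooled).min() <= 1e-12 * max(1.0, np.abs(pooled).max()):
        raise ValueError("singular pooled covariance; classes are degenerate")
    m0, m1 = means[classes[0]], means[classes[1]]
    w = np.linalg.solve(pooled, m1 - m0)
    c = -0.5 * float(w @ (m0 + m1))  # equal priors
    return LdaModel(labels=(classes[0], classes[1]), means=means,
                    pooled_cov=pooled, weights=w, bias=c)


def boundary_line(m: LdaModel, positive_label: str | None = None) -> DiscriminantLine:
    """Solve the equal-posterior locus w.(x, y) + c = 0 for y = a*x + b.

    ``positive_label`` defaults to the class on the higher-y (convexity)
    side of the line.
    """
    w, c = m.weights, m.bias
    if abs(w[1]) <= 1e-300 or abs(w[1]) < 1e-12 * abs(w[0]):
        raise ValueError(
            "decision boundary is vertical (y-coefficient ~ 0); "
            "no y = a*x + b form exists — use the general-form weights instead"
        )
    a = -w[0] / w[1]
    b = -c / w[1]
    upper = m.labels[1] if w[1] > 0 else m.labels[0]
    lower = m.labels[0] if upper == m.labels[1] else m.labels[1]
    if positive_label is None:
        positive_label = upper
    elif positive_label not in m.labels:
        raise ValueError(f"unknown label {positive_label!r}")
    negative = lower if positive_label == upper else upper
    return DiscriminantLine(a=float(a), b=float(b),
                            positive_label=str(positive_label),
                            negative_label=str(negative))


def classify_point(line: DiscriminantLine, x: float, y: float) -> str:
    """Classify one (solidity, convexity) point; ties go to positive_label."""
    if not (np.isfinite(x) and np.isfinite(y)):
        raise ValueError("inputs must be finite")
    return line.positive_label if y >= line.a * x + line.b else line.negative_label


# ---------------------------------------------------------------------------
# agreement statistics


def confusion(truth: Sequence[str], predicted: Sequence[str],
              labels: Sequence[str] | None = None) -> ConfusionMatrix:
    """2x2 confusion matrix of true vs predicted labels."""
    truth = list(map(str, truth))
    predicted = list(map(str, predicted))
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted must have equal length")
    if labels is None:
        labels = sorted(set(truth) | set(predicted))
    labels = tuple(map(str, labels))
    if len(labels) != 2:
        raise ValueError(f"exactly two labels required, got {labels}")
    idx = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((2, 2), dtype=np.int64)
    for t, p in zip(truth, predicted):
        counts[idx[t], idx[p]] += 1
    return ConfusionMatrix(labels=labels, counts=counts)


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of agreeing predictions: trace / total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e),
    with p_e from the product of row/column marginals."""
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = accuracy(cm)
    rows = cm.counts.sum(axis=1) / n
    cols = cm.counts.sum(axis=0) / n
    p_e = float(rows @ cols)
    if p_e >= 1.0:
        raise ValueError("kappa undefined: chance agreement is 1 (degenerate marginals)")
    return (p_o - p_e) / (1.0 - p_e)


def kappa_from_accuracy(acc: float, chance: float = 0.5) -> float:
    """Kappa as a function of overall accuracy at fixed chance agreement.

    For a balanced two-class design (equal true marginals) chance
    agreement is exactly 1/2 whatever the error split, so
    kappa = 2*accuracy - 1.
    """
    if not 0.0 <= acc <= 1.0:
        raise ValueError(f"accuracy out of [0, 1]: {acc}")
    if chance >= 1.0:
        raise ValueError("kappa undefined: chance agreement is 1")
    return (acc - chance) / (1.0 - chance)


# ---------------------------------------------------------------------------
# group comparison


def student_t_test(group_a: Sequence[float], group_b: Sequence[float],
                   equal_var: bool = True) -> TestResult:
    """Two-sample t-test, two-sided.

    ``equal_var=True`` (default) is Student's pooled-variance test;
    ``False`` is Welch's with Satterthwaite degrees of freedom.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if equal_var:
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        if sp2 <= 0:
            raise ValueError("zero pooled variance; t statistic undefined")
        se = math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    else:
        if va == 0 and vb == 0:
            raise ValueError("zero variance in both groups; t statistic undefined")
        se = math.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    t = (a.mean() - b.mean()) / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TestResult(statistic=float(t), df=float(df), p_value=min(p, 1.0))


def relative_to_reference(records: Sequence, reference_label: str) -> list:
    """Divide V, Vc, A, Ac of every record by the reference group's means.

    The reference group's mean of each normalized quantity becomes exactly
    1; C and S are untouched (already dimensionless).
    """
    import dataclasses

    ref = [r for r in records if r.label == reference_label]
    if not ref:
        raise ValueError(f"no records with reference label {reference_label!r}")
    means = {f: float(np.mean([getattr(r, f) for r in ref]))
             for f in ("V", "Vc", "A", "Ac")}
    out = []
    for r in records:
        out.append(dataclasses.replace(
            r, **{f: getattr(r, f) / means[f] for f in means}))
    return out
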