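"""Prognostic-index risk stratification and univariate Cox gene screening.

A gene signature assigns a weight ``beta_j`` to each of q genes; the
prognostic index of a subject with expression values ``x_1 ... x_q`` is
the linear predictor

    PI = beta_1 * x_1 + ... + beta_q * x_q,

with high PI indicating high risk of death.  Subjects with PI <= c form
the good-prognosis (low-risk) group and PI > c the poor-prognosis
(high-risk) group, where the cutoff c defaults to the median PI of the
training cohort.

The screening step fits, gene by gene, the univariate proportional-hazards
model h(t | x) = h0(t) exp(beta * x) by partial likelihood (Breslow tie
handling, via lifelines) and retains genes whose two-sided Wald p-value
falls below a threshold, with the fitted coefficients as signature weights.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from .survival_data import CensoredSample

__all__ = [
    "GeneSignature",
    "RiskSplit",
    "prognostic_index",
    "median_cutoff",
    "split_groups",
    "concordance_index",
    "univariate_cox_screen",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSignature:
    """Ordered gene symbols with per-gene coefficients beta_j."""

    genes: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        genes = tuple(str(g) for g in self.genes)
        weights = np.asarray(self.weights, dtype=float)
        if len(genes) == 0:
            raise ValueError("signature must contain at least one gene")
        if len(set(genes)) != len(genes):
            raise ValueError("signature gene names must be unique")
        if weights.shape != (len(genes),) or not np.all(np.isfinite(weights)):
            raise ValueError("weights must be finite, one per gene")
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "weights", weights)

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_csv(cls, path) -> "GeneSignature":
        """Read a gene,weight CSV (header required)."""
        df = pd.read_csv(path)
        return cls(genes=tuple(df.iloc[:, 0].astype(str)), weights=df.iloc[:, 1])

    def to_csv(self, path) -> None:
        pd.DataFrame({"gene": self.genes, "weight": self.weights}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class RiskSplit:
    """Partition of subjects into good (PI <= c) and poor (PI > c) groups."""

    cutoff: float
    good_idx: np.ndarray
    poor_idx: np.ndarray

    @property
    def n_good(self) -> int:
        return int(self.good_idx.size)

    @property
    def n_poor(self) -> int:
        return int(self.poor_idx.size)

    @property
    def testable(self) -> bool:
        """Both groups nonempty, so a two-group comparison is defined."""
        return self.n_good > 0 and self.n_poor > 0


def prognostic_index(expr: pd.DataFrame, sig: GeneSignature) -> np.ndarray:
    """PI_i = sum_j weight_j * expr_ij for every subject (row) in expr.

    Raises ``KeyError`` listing the missing gene columns if the expression
    table does not cover the signature.
    """
    missing = [g for g in sig.genes if g not in expr.columns]
    if missing:
        raise KeyError(f"expression table is missing signature genes: {missing}")
    x = expr.loc[:, list(sig.genes)].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("signature gene columns contain missing values")
    return x @ sig.weights


def median_cutoff(training_pis) -> float:
    """Sample median of the training-cohort PIs (the recommended cutoff)."""
    return quantile_cutoff(training_pis, 0.5)


def quantile_cutoff(training_pis, q: float) -> float:
    """Quantile of the training PIs, for sensitivity to the cutoff itself.

    The median (q = 0.5) is the recommended default; quartile cutoffs
    (q = 0.25 or 0.75) typically separate the groups less clearly and
    unbalance the group sizes.
    """
    pis = np.asarray(training_pis, dtype=float)
    if pis.size == 0:
        raise ValueError("need at least one training PI value")
    if not 0.0 <= q <= 1.0:
        raise ValueError("cutoff quantile must lie in [0, 1]")
    return float(np.quantile(pis, q))


def split_groups(sample: CensoredSample, cutoff: float) -> RiskSplit:
    """Split by PI: good = {PI <= c}, poor = {PI > c}; ties at c go good.

    An empty group is allowed but flagged via ``RiskSplit.testable`` (and a
    warning), since downstream two-group tests are then undefined.
    """
    if sample.pi is None:
        raise ValueError("sample has no prognostic-index values")
    good = np.flatnonzero(sample.pi <= cutoff)
    poor = np.flatnonzero(sample.pi > cutoff)
    split = RiskSplit(cutoff=float(cutoff), good_idx=good, poor_idx=poor)
    if not split.testable:
        warnings.warn(
            f"cutoff {cutoff} leaves an empty risk group "
            f"(n_good={split.n_good}, n_poor={split.n_poor}); "
            "two-group testing is undefined",
            stacklevel=2,
        )
    return split


def concordance_index(pis, sample: CensoredSample) -> float:
    """Harrell's c-index of the PI against observed survival.

    Over usable pairs (those whose smaller observed time is an event), the
    fraction where the shorter-lived subject has the higher PI; PI ties
    count 1/2.  Raises when no pair is usable.
    """
    pis = np.asarray(pis, dtype=float)
    if pis.shape != sample.time.shape:
        raise ValueError("pis and sample must have equal length")
    t, d = sample.time, sample.status
    # pair (i, j) usable iff t_i < t_j and d_i = 1 (or symmetric), or
    # t_i == t_j with exactly one event
    conc = disc = ties = 0
    n = len(sample)
    for i in range(n):
        if d[i] != 1:
            continue
        earlier = (t > t[i]) | ((t == t[i]) & (d == 0))
        hi = pis[i] > pis[earlier]
        lo = pis[i] < pis[earlier]
        conc += int(hi.sum())
        disc += int(lo.sum())
        ties += int(earlier.sum() - hi.sum() - lo.sum())
    usable = conc + disc + ties
    if usable == 0:
        raise ValueError("no usable pairs: concordance index is undefined")
    return (conc + 0.5 * ties) / usable


def univariate_cox_screen(
    expr: pd.DataFrame,
    sample: CensoredSample,
    p_threshold: float = 0.05,
) -> GeneSignature:
    """Screen genes one at a time by univariate Cox regression.

    Fits h(t|x_j) = h0j(t) exp(beta_j x_j) per gene (partial likelihood,
    Breslow ties), computes the two-sided Wald p-value for beta_j = 0, and
    returns the signature of genes with p < ``p_threshold`` with the
    fitted coefficients as weights.  Conventional thresholds are 0.05,
    0.01 and 0.001.  Genes with non-convergent (monotone-likelihood) fits
    are excluded and logged.
    """
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must lie strictly between 0 and 1")
    if len(expr) != len(sample):
        raise ValueError("expression table and sample must have equal length")
    selected: list[str] = []
    weights: list[float] = []
    base = pd.DataFrame({"time": sample.time, "status": sample.status})
    for gene in expr.columns:
        df = base.assign(x=expr[gene].to_numpy(dtype=float))
        fitter = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fitter.fit(
                    df,
                    duration_col="time",
                    event_col="status",
                    # tight Newton tolerances: the screen's coefficients
                    # become signature weights, so solve to near machine
                    # precision rather than the looser display default
                    fit_options={"precision": 1e-12, "r_precision": 1e-15},
                )
        except (ConvergenceError, ValueError) as exc:
            logger.warning("gene %s: non-convergent Cox fit, excluded (%s)", gene, exc)
            continue
        beta = float(fitter.params_.loc["x"])
        p = float(fitter.summary.loc["x", "p"])
        if not np.isfinite(beta) or abs(beta) > 50:
            logger.warning("gene %s: infinite-estimate flag, excluded", gene)
            continue
        if p < p_threshold:
            selected.append(str(gene))
            weights.append(beta)
    if not selected:
        raise ValueError(f"no gene passed the p < {p_threshold} screen")
    return GeneSignature(genes=tuple(selected), weights=np.asarray(weights))
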