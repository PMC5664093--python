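"""Gene-embedded PCA and unsupervised feature extraction.

In this feature-extraction scheme the probes (genes), not the samples, are
embedded into the low-dimensional space: the PC *scores* u_k are the
eigenvectors of X X^T (one component per probe), and the PC *loadings*
v_k = X^T u_k, attributed to samples, are eigenvectors of X^T X with the
same eigenvalues.  The discriminative PC is found by a two-group t-test on
each loading vector; probes are then scored by the standardized squared
score (u_ki / sigma_k)^2 referred to a chi-squared distribution with one
degree of freedom, BH-adjusted, and selected below an adjusted-p cutoff.

The decomposition is computed by a thin SVD of the column-normalized
matrix rather than by forming the probe-by-probe covariance X X^T, which
is numerically stabler and far cheaper for matrices with ~10^4-10^5 probes
and ~20 samples; the eigenpairs are mathematically identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix, SampleGroups

__all__ = [
    "GeneEmbedding",
    "PCIdentification",
    "ProbeSelection",
    "decompose",
    "identify_discriminative_pc",
    "chi2_pvalues",
    "score_chi2",
    "bh_adjust",
    "select_probes",
]


@dataclass
class GeneEmbedding:
    """Eigenpairs of X X^T with sample-side loadings.

    eigenvalues -- lambda_k >= 0, non-increasing
    scores      -- (n_probes, k) matrix; column k is the unit vector u_k
    loadings    -- (n_samples, k) matrix; column k is v_k = X^T u_k
    """

    eigenvalues: np.ndarray
    scores: np.ndarray
    loadings: np.ndarray
    probe_ids: list
    sample_ids: list

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    def loading(self, pc_index: int) -> pd.Series:
        """Sample-side loading vector v_k for 1-based ``pc_index``."""
        return pd.Series(self.loadings[:, pc_index - 1], index=self.sample_ids)

    def score(self, pc_index: int) -> pd.Series:
        """Probe-side score vector u_k for 1-based ``pc_index``."""
        return pd.Series(self.scores[:, pc_index - 1], index=self.probe_ids)


@dataclass
class PCIdentification:
    """Result of scanning PC loadings for group separation."""

    pc_index: int  # 1-based index of the selected PC
    pvalues: np.ndarray  # t-test p-value per PC, index k-1
    group_labels: tuple
    t_test: str = "welch"
    overridden: bool = False


@dataclass
class ProbeSelection:
    """Per-probe chi-squared statistics, p-values, and selection flags.

    ``table`` is indexed by probe id with columns ``statistic``, ``pvalue``
    and, once thresholded, ``adjusted_pvalue`` and ``selected``.  ``sigma``
    is the standard deviation of the chosen PC score components used to
    standardize the statistic.
    """

    table: pd.DataFrame
    sigma: float
    pc_index: int
    threshold: Optional[float] = None
    pc_identification: Optional[PCIdentification] = field(default=None, compare=False)

    @property
    def selected_probes(self) -> list:
        return list(self.table.index[self.table["selected"]])


def decompose(m: ExpressionMatrix, n_components: Optional[int] = None) -> GeneEmbedding:
    """Eigendecompose X X^T via thin SVD of X (probes x samples).

    Returns eigenpairs ordered by non-increasing eigenvalue.  Each score
    vector's sign is fixed so that its largest-magnitude component is
    positive (signs are mathematically arbitrary; the convention makes
    output reproducible, and the downstream squared statistic is
    sign-invariant anyway).  Requesting more components than the matrix
    rank pads with zero eigenvalues/vectors and a warning.
    """
    X = m.values
    n_avail = min(X.shape)
    if n_components is None:
        n_components = m.n_samples
    if n_components < 1:
        raise ValueError("n_components must be positive")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    lam = s**2
    # v_k = X^T u_k = s_k * V[:, k]
    V = Vt.T * s
    k = min(n_components, n_avail)
    U, lam, V = U[:, :k], lam[:k], V[:, :k]
    for j in range(k):
        i = int(np.argmax(np.abs(U[:, j])))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
            V[:, j] = -V[:, j]
    if n_components > n_avail:
        warnings.warn(
            f"requested {n_components} components but rank is at most "
            f"{n_avail}; surplus eigenvalues returned as 0",
            stacklevel=2,
        )
        pad = n_components - n_avail
        lam = np.concatenate([lam, np.zeros(pad)])
        U = np.hstack([U, np.zeros((U.shape[0], pad))])
        V = np.hstack([V, np.zeros((V.shape[0], pad))])
    return GeneEmbedding(lam, U, V, m.probe_ids, m.sample_ids)


def identify_discriminative_pc(
    e: GeneEmbedding,
    g: SampleGroups,
    max_pc: Optional[int] = None,
    t_test: str = "welch",
    override: Optional[int] = None,
) -> PCIdentification:
    """Find the PC whose sample loading best separates the two groups.

    Runs a two-group t-test on v_k for k = 1..max_pc and returns all
    p-values with ``pc_index`` = argmin p (ties break to the smallest k).
    ``t_test`` selects the unequal-variance Welch form (default) or the
    pooled-variance Student form.  ``override`` forces a specific PC while
    still reporting the scan.
    """
    g.check_covers(e.sample_ids)
    labels = g.labels
    idx = {lab: [i for i, s in enumerate(e.sample_ids) if g.assignments[s] == lab] for lab in labels}
    for lab in labels:
        if len(idx[lab]) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 samples; t-test undefined")
    if t_test not in ("welch", "pooled"):
        raise ValueError(f"unknown t_test variant {t_test!r}")
    if max_pc is None:
        max_pc = e.n_components
    max_pc = min(max_pc, e.n_components)
    pvals = np.empty(max_pc)
    for k in range(max_pc):
        a = e.loadings[idx[labels[0]], k]
        b = e.loadings[idx[labels[1]], k]
        pvals[k] = stats.ttest_ind(a, b, equal_var=(t_test == "pooled")).pvalue
    if override is not None:
        if not 1 <= override <= e.n_components:
            raise ValueError(f"pc override {override} outside 1..{e.n_components}")
        return PCIdentification(override, pvals, labels, t_test, overridden=True)
    pc_index = int(np.nanargmin(pvals)) + 1
    return PCIdentification(pc_index, pvals, labels, t_test)


def score_chi2(u: np.ndarray, center: bool = True, df: int = 1) -> tuple[np.ndarray, np.ndarray, float]:
    """Chi-squared attribution for one PC score vector.

    sigma is the sample standard deviation of the components of ``u``
    (mean-subtracted with the n-1 denominator by default; ``center=False``
    uses the root mean square about zero, for sensitivity analysis).  The
    per-probe statistic is (u_i / sigma)^2 and the p-value its upper-tail
    chi-squared(df) probability.  Returns (statistic, pvalues, sigma).
    """
    u = np.asarray(u, dtype=float)
    if u.size < 2:
        raise ValueError("need at least 2 probes to estimate sigma")
    if center:
        sigma = float(np.std(u, ddof=1))
    else:
        sigma = float(np.sqrt(np.sum(u**2) / (u.size - 1)))
    if sigma == 0:
        raise ValueError("PC score vector has zero spread")
    statistic = (u / sigma) ** 2
    pvalues = stats.chi2.sf(statistic, df)
    return statistic, pvalues, sigma


def chi2_pvalues(
    e: GeneEmbedding, pc_index: int, center: bool = True, df: int = 1
) -> ProbeSelection:
    """Attribute chi-squared p-values to probes from PC ``pc_index`` scores."""
    if not 1 <= pc_index <= e.n_components:
        raise ValueError(f"pc_index {pc_index} outside 1..{e.n_components}")
    u = e.scores[:, pc_index - 1]
    statistic, pvalues, sigma = score_chi2(u, center=center, df=df)
    table = pd.DataFrame(
        {"statistic": statistic, "pvalue": pvalues},
        index=pd.Index(e.probe_ids, name="probe_id"),
    )
    return ProbeSelection(table, sigma, pc_index)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1, where p_(j) are
    the sorted raw p-values.  Values outside [0, 1] are an error.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_probes(
    m: ExpressionMatrix,
    g: SampleGroups,
    threshold: float = 0.01,
    pc_index: Optional[int] = None,
    t_test: str = "welch",
    max_pc: Optional[int] = None,
    center: bool = True,
    df: int = 1,
) -> ProbeSelection:
    """End-to-end probe selection on a sample-normalized matrix.

    Composes :func:`decompose`, :func:`identify_discriminative_pc`
    (respecting a manual ``pc_index`` override), :func:`chi2_pvalues` and
    :func:`bh_adjust`; probes with adjusted p strictly below ``threshold``
    are flagged selected.  Deterministic given its input.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    emb = decompose(m)
    ident = identify_discriminative_pc(emb, g, max_pc=max_pc, t_test=t_test, override=pc_index)
    sel = chi2_pvalues(emb, ident.pc_index, center=center, df=df)
    adj = bh_adjust(sel.table["pvalue"].to_numpy())
    sel.table["adjusted_pvalue"] = adj
    sel.table["selected"] = adj < threshold
    sel.threshold = threshold
    sel.pc_identification = ident
    return sel
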