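"""Core in-memory containers for multi-tissue eQTL analysis.

The central objects are an :class:`ExpressionBlock` — one gene's expression
matrix across ``n`` subjects and ``t`` tissues with an explicit missingness
mask — and a :class:`GenotypeVector` — one SNP's minor-allele dosages across
the same subjects.  Both are plain dataclasses wrapping numpy arrays; all
heavier machinery (null fits, score tests) lives in :mod:`tissueqtl.model`
and :mod:`tissueqtl.score`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidCovarianceError

__all__ = [
    "ExpressionBlock",
    "GenotypeVector",
    "CovStructure",
]


@dataclass
class ExpressionBlock:
    """Expression of one gene: subjects x tissues, with missing entries.

    Parameters
    ----------
    values : ndarray, shape (n, t)
        Expression values (typically covariate-residualised log intensities).
        Entries at masked positions are ignored (stored as NaN).
    mask : ndarray of bool, shape (n, t), optional
        True where the subject-tissue pair was observed.  Defaults to
        ``~isnan(values)``.
    subject_ids, tissue_ids : sequence of str, optional
        Identifiers; default to ``S0..S{n-1}`` / ``T0..T{t-1}``.
    """

    values: np.ndarray
    mask: Optional[np.ndarray] = None
    subject_ids: Optional[Sequence[str]] = None
    tissue_ids: Optional[Sequence[str]] = None

    def __post_init__(self):
        v = np.array(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("expression values must be a 2-D (subjects x tissues) array")
        if self.mask is None:
            m = ~np.isnan(v)
        else:
            m = np.array(self.mask, dtype=bool)
            if m.shape != v.shape:
                raise ValueError("mask shape must match values shape")
            m &= ~np.isnan(v)
        n, t = v.shape
        if n < 2:
            raise ValueError("need at least 2 subjects")
        if t < 1:
            raise ValueError("need at least 1 tissue")
        v = np.where(m, v, np.nan)
        self.values = v
        self.mask = m
        if self.subject_ids is None:
            self.subject_ids = [f"S{i}" for i in range(n)]
        if self.tissue_ids is None:
            self.tissue_ids = [f"T{j}" for j in range(t)]
        self.subject_ids = list(self.subject_ids)
        self.tissue_ids = list(self.tissue_ids)
        if len(self.subject_ids) != n or len(self.tissue_ids) != t:
            raise ValueError("identifier lengths must match matrix shape")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_tissues(self) -> int:
        return self.values.shape[1]

    @property
    def tissues_per_subject(self) -> np.ndarray:
        """Number of observed tissues per subject (length n)."""
        return self.mask.sum(axis=1)

    def drop_empty_subjects(self) -> "ExpressionBlock":
        """Return a copy without subjects that have no observed tissue."""
        keep = self.tissues_per_subject > 0
        if keep.all():
            return self
        return ExpressionBlock(
            self.values[keep],
            self.mask[keep],
            [s for s, k in zip(self.subject_ids, keep) if k],
            self.tissue_ids,
        )


@dataclass
class GenotypeVector:
    """One SNP's dosages (minor-allele counts, 0/1/2) for n subjects.

    Missing dosages are NaN.  ``maf`` is computed from the non-missing
    entries if not supplied.
    """

    dosages: np.ndarray
    snp_id: str = "snp"
    chrom: str = "1"
    pos: int = 1
    maf: Optional[float] = None

    def __post_init__(self):
        d = np.array(self.dosages, dtype=float).ravel()
        obs = d[~np.isnan(d)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        if self.pos < 1:
            raise ValueError("pos must be a 1-based coordinate (>= 1)")
        self.dosages = d
        if self.maf is None:
            if obs.size:
                af = obs.mean() / 2.0
                self.maf = float(min(af, 1.0 - af))
            else:
                self.maf = 0.0
        if not (0.0 <= self.maf <= 0.5):
            raise ValueError("maf must lie in [0, 0.5]")

    @property
    def n_subjects(self) -> int:
        return self.dosages.size

    def is_degenerate(self) -> bool:
        """True if fewer than two distinct dosages are observed."""
        obs = self.dosages[~np.isnan(self.dosages)]
        return np.unique(obs).size < 2


@dataclass(frozen=True)
class CovStructure:
    """Compound-symmetry variance components of the null model.

    Each subject's t_i x t_i covariance block is ``epsilon*I + tau*11'``:
    ``tau`` is the subject random-intercept variance (shared across tissues)
    and ``epsilon`` the independent residual variance.
    """

    tau: float
    epsilon: float

    def __post_init__(self):
        if not np.isfinite(self.epsilon) or self.epsilon <= 0:
            raise InvalidCovarianceError(f"epsilon must be > 0, got {self.epsilon}")
        if not np.isfinite(self.tau) or self.tau < 0:
            raise InvalidCovarianceError(f"tau must be >= 0, got {self.tau}")

    def shrink(self, t_i) -> np.ndarray:
        """tau/(epsilon + t_i*tau), the Woodbury shrinkage factor per block size."""
        t_i = np.asarray(t_i, dtype=float)
        return self.tau / (self.epsilon + t_i * self.tau)
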