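"""Refitting of SBS96 catalogs against a reference signature matrix.

The catalog is normalized to channel proportions and decomposed as a
non-negative mixture of reference signatures with total weight at most 1;
weights below the cutoff (default 0.06) are zeroed and the surviving set
is refit once.  Mismatch-repair deficiency is flagged when the combined
weight of the MMRd-associated signatures (6, 15, 20 and 26 in the v2
reference naming) reaches 0.05; homologous-recombination deficiency when
signature 3 alone reaches the same threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .types import ValidationError

DEFAULT_CUTOFF = 0.06
MMRD_SIGNATURES = ("Signature_6", "Signature_15", "Signature_20", "Signature_26")
BRCA2D_SIGNATURE = "Signature_3"
COMBINED_WEIGHT_THRESHOLD = 0.05


@dataclass
class SignatureMatrix:
    """96 SBS channels (rows, canonical order) x named signature columns."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.frame.shape[0] != 96:
            raise ValidationError(f"signature matrix must have 96 rows, got {self.frame.shape[0]}")
        sums = self.frame.sum(axis=0)
        if (self.frame.values < -1e-12).any():
            raise ValidationError("signature probabilities must be non-negative")
        bad = sums[(sums - 1.0).abs() > 1e-6]
        if not bad.empty:
            raise ValidationError(f"signature columns must sum to 1: {list(bad.index)}")

    @property
    def names(self) -> list[str]:
        return list(self.frame.columns)

    @classmethod
    def read_tsv(cls, path) -> "SignatureMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="channel")


@dataclass
class SignatureWeights:
    weights: pd.Series           # per-signature weight in [0, 1]
    residual: float              # RMSE between fitted mixture and catalog proportions
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        if (self.weights < -1e-9).any():
            raise ValidationError("weights must be non-negative")
        if self.weights.sum() > 1 + 1e-6:
            raise ValidationError("weights must sum to at most 1")
        if self.residual < 0:
            raise ValidationError("residual must be non-negative")


def _nnls_sum_constrained(S: np.ndarray, p: np.ndarray) -> np.ndarray:
    """argmin ||S w - p||  s.t.  w >= 0, sum(w) <= 1."""
    w, _ = optimize.nnls(S, p)
    if w.sum() <= 1 + 1e-9:
        return w
    res = optimize.minimize(
        lambda x: 0.5 * np.sum((S @ x - p) ** 2),
        x0=w / w.sum(),
        jac=lambda x: S.T @ (S @ x - p),
        bounds=[(0.0, 1.0)] * S.shape[1],
        constraints=[{"type": "ineq", "fun": lambda x: 1.0 - x.sum()}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-14},
    )
    return np.clip(res.x, 0.0, None)


def fit_signature_weights(
    catalog_sbs,
    signatures: SignatureMatrix,
    cutoff: float = DEFAULT_CUTOFF,
) -> SignatureWeights:
    """Fit reference-signature weights to an SBS96 catalog.

    ``catalog_sbs`` is the 96-vector of counts (or a pd.Series indexed by
    channel names matching the matrix rows).  The fit is sum-constrained
    NNLS on the catalog proportions, followed by one cutoff-and-refit
    pass: weights below ``cutoff`` are zeroed and the surviving
    signatures refit.
    """
    if isinstance(catalog_sbs, pd.Series):
        if list(catalog_sbs.index) != list(signatures.frame.index):
            raise ValidationError("catalog channel order does not match signature matrix")
        counts = catalog_sbs.to_numpy(dtype=float)
    else:
        counts = np.asarray(catalog_sbs, dtype=float)
    if counts.shape != (96,):
        raise ValidationError(f"catalog must have 96 channels, got {counts.shape}")
    total = counts.sum()
    if total <= 0:
        raise ValidationError("cannot fit signatures to an empty catalog")
    p = counts / total
    S = signatures.frame.to_numpy(dtype=float)

    w = _nnls_sum_constrained(S, p)
    keep = w >= cutoff
    w_final = np.zeros_like(w)
    if keep.any():
        w_final[keep] = _nnls_sum_constrained(S[:, keep], p)
    residual = float(np.sqrt(np.mean((S @ w_final - p) ** 2)))
    return SignatureWeights(
        weights=pd.Series(w_final, index=signatures.names),
        residual=residual,
        cutoff=cutoff,
    )


def mmrd_combined_weight(
    weights: SignatureWeights,
    signature_names: tuple[str, ...] = MMRD_SIGNATURES,
    threshold: float = COMBINED_WEIGHT_THRESHOLD,
) -> tuple[float, bool]:
    """Combined weight of the MMRd-associated signatures and its flag."""
    missing = [s for s in signature_names if s not in weights.weights.index]
    if missing:
        raise ValidationError(f"signatures absent from matrix: {missing}")
    combined = float(weights.weights[list(signature_names)].sum())
    return combined, combined >= threshold


def brca2d_signature_flag(
    weights: SignatureWeights,
    signature_name: str = BRCA2D_SIGNATURE,
    threshold: float = COMBINED_WEIGHT_THRESHOLD,
) -> bool:
    """True when the HRD signature's weight reaches the threshold."""
    if signature_name not in weights.weights.index:
        raise ValidationError(f"signature absent from matrix: {signature_name}")
    return float(weights.weights[signature_name]) >= threshold
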