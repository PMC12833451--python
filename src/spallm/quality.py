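"""Data-quality degradation by masking non-zero expression entries.

Quality tiers Q0-Q4 zero out 0%, 50%, 75%, 87.5% and 93.75% of the non-zero
entries of the raw count matrix, emulating progressively sparser capture.
Masking is entry-wise zeroing of observed values, not count thinning: exactly
``floor(fraction * nnz)`` entries drawn uniformly without replacement are set
to zero and every other entry is left bit-identical.
"""

from __future__ import annotations

import numpy as np

from .types import ExpressionMatrix, ValidationError

#: Fraction of non-zero entries masked at each named quality level.
QUALITY_LEVELS: dict[str, float] = {
    "Q0": 0.0,
    "Q1": 0.5,
    "Q2": 0.75,
    "Q3": 0.875,
    "Q4": 0.9375,
}


def mask_expression(X: ExpressionMatrix, fraction: float, seed: int = 0) -> ExpressionMatrix:
    """Zero out ``floor(fraction * nnz)`` uniformly chosen non-zero entries."""
    if not 0.0 <= fraction <= 1.0:
        raise ValidationError(f"mask fraction must be in [0, 1], got {fraction}")
    values = X.values.copy()
    nz_rows, nz_cols = np.nonzero(values)
    n_mask = int(np.floor(fraction * nz_rows.size))
    if n_mask:
        rng = np.random.default_rng(seed)
        pick = rng.choice(nz_rows.size, size=n_mask, replace=False)
        values[nz_rows[pick], nz_cols[pick]] = 0.0
    return ExpressionMatrix(
        values=values,
        spot_ids=list(X.spot_ids),
        gene_symbols=list(X.gene_symbols),
        is_normalized=X.is_normalized,
    )


def density(X: ExpressionMatrix) -> float:
    """Fraction of non-zero entries, ``nnz / (n * m)``."""
    return float(np.count_nonzero(X.values)) / X.values.size


def quality_grid(X: ExpressionMatrix, seed: int = 0, nested: bool = False
                 ) -> dict[str, ExpressionMatrix]:
    """One masked matrix per quality level Q0-Q4.

    By default each level is masked independently from the ORIGINAL matrix
    with a level-specific derived seed; ``nested=True`` instead masks each
    level on top of the previous one (mask supports then satisfy
    Q4 <= Q3 <= ... <= Q0).
    """
    ss = np.random.SeedSequence(seed)
    level_seeds = ss.generate_state(len(QUALITY_LEVELS)) % (2**31)
    out: dict[str, ExpressionMatrix] = {}
    prev = X
    for (name, frac), lseed in zip(QUALITY_LEVELS.items(), level_seeds):
        if frac == 0.0:
            out[name] = X
            continue
        if nested:
            # incremental fraction so the cumulative mask hits `frac` of the
            # original support: nnz targets are halved at each tier
            target_nnz = int(np.floor((1 - frac) * np.count_nonzero(X.values)))
            cur_nnz = np.count_nonzero(prev.values)
            inc = 0.0 if cur_nnz == 0 else 1.0 - target_nnz / cur_nnz
            out[name] = mask_expression(prev, inc, seed=int(lseed))
            prev = out[name]
        else:
            out[name] = mask_expression(X, frac, seed=int(lseed))
    return out
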