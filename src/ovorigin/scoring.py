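"""Signature scoring: per-gene z-scores and the combined FT-O score.

Log-expression is scaled and centred per gene (z-score over samples, n-1
denominator, computed within each dataset independently), each signature's
score is the mean z over its member genes, and the combined cell-of-origin
score subtracts the OSE-tumor score from the FTE-tumor score — positive
values mean greater FTE character.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from .datatypes import Signature, SignatureSet, ValidationError


class ZScoreResult(NamedTuple):
    z: pd.DataFrame
    constant_genes: list[str]  # rows with zero variance, mapped to all-zero z


def zscore_rows(log_expression: pd.DataFrame) -> ZScoreResult:
    """Per-gene z-scores across samples (sd with n-1 denominator).

    Constant rows map to all-zero z and are flagged rather than dropped, so
    signature coverage does not drift between samples.
    """
    if log_expression.shape[1] < 2:
        raise ValidationError("z-scoring needs at least 2 samples")
    values = log_expression.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    constant = sd[:, 0] == 0
    safe_sd = np.where(constant[:, None], 1.0, sd)
    z = (values - mean) / safe_sd
    z[constant] = 0.0
    return ZScoreResult(
        z=pd.DataFrame(z, index=log_expression.index, columns=log_expression.columns),
        constant_genes=list(log_expression.index[constant]),
    )


class SignatureScore(NamedTuple):
    scores: pd.Series  # per-sample mean z over present signature genes
    coverage: float  # fraction of signature genes found in the matrix
    missing: list[str]


def signature_score(z: pd.DataFrame, signature: Signature) -> SignatureScore:
    """Per-sample mean z over the signature's genes present in the matrix."""
    present = [g for g in signature.genes if g in z.index]
    if not present:
        raise ValidationError(
            f"no gene of signature {signature.name} found in the expression matrix"
        )
    missing = [g for g in signature.genes if g not in z.index]
    scores = z.loc[present].mean(axis=0)
    scores.name = f"{signature.group}_score"
    return SignatureScore(
        scores=scores,
        coverage=len(present) / len(signature.genes),
        missing=missing,
    )


def combined_score(ft_scores: pd.Series, o_scores: pd.Series) -> pd.Series:
    """FT-O cell-of-origin score: FTE-tumor score minus OSE-tumor score."""
    if set(ft_scores.index) != set(o_scores.index):
        raise ValidationError("FT and O scores cover different samples")
    diff = ft_scores - o_scores.loc[ft_scores.index]
    diff.name = "ft_minus_o"
    return diff


def score_samples(
    log_expression: pd.DataFrame,
    signatures: SignatureSet,
    k: int,
    ft_group: str = "T-FT",
    o_group: str = "T-O",
) -> pd.DataFrame:
    """Score table: sample, ft_score, o_score, ft_minus_o, coverages.

    z-scores are computed genome-wide on this matrix (identical per gene to
    scoring restricted to signature genes), then averaged over each
    signature.
    """
    z, _ = zscore_rows(log_expression)
    ft = signature_score(z, signatures.get(ft_group, k))
    o = signature_score(z, signatures.get(o_group, k))
    table = pd.DataFrame(
        {
            "sample": z.columns,
            "ft_score": ft.scores.to_numpy(),
            "o_score": o.scores.to_numpy(),
            "ft_minus_o": combined_score(ft.scores, o.scores).to_numpy(),
            "coverage_ft": ft.coverage,
            "coverage_o": o.coverage,
        }
    )
    return table
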