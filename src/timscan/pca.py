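"""PCA of mutational-scan and alignment-frequency matrices.

The experimental object is an 80 x 20 matrix: library positions by
amino-acid outcomes, holding selection coefficients (or log-transformed
alignment frequencies). Principal components are extracted by singular
value decomposition of the normalized matrix; per-position scores are
then correlated with sequence/structure features (hydrophobicity,
conservation, information content, ASA/RSA, b-factor) and averaged over
the TIM barrel's four-fold symmetry cells.

Two normalizations are offered. ``per_position_z`` gives every position
the same mean and s.d. (each row z-scored); ``per_column_center`` only
centers each outcome column, which preserves between-position mean
differences so the first component can track average fitness. The choice
is always recorded in the result.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .alphabet import AA20
from .annotate import fourfold_index

NORMALIZATIONS = ("per_position_z", "per_column_center")


def impute_row_mean(matrix: pd.DataFrame) -> pd.DataFrame:
    """Fill missing cells with their row mean (PCA needs complete matrices)."""
    if matrix.isna().all(axis=1).any():
        raise ValueError("a row is entirely missing; cannot impute")
    means = matrix.mean(axis=1)
    return matrix.apply(lambda col: col.fillna(means))


@dataclasses.dataclass
class PCAResult:
    """Scores, loadings and variance fractions of one decomposition.

    ``scores`` is (n_rows, k) with component scores per position;
    ``loadings`` is (k, n_cols); ``normalized`` keeps the matrix that was
    decomposed (so scores @ loadings reconstructs it). The sign of each
    component is fixed so its loading vector has a non-negative sum.
    """

    scores: np.ndarray
    loadings: np.ndarray
    variance_fractions: np.ndarray
    normalization: str
    normalized: np.ndarray
    row_index: tuple
    columns: tuple

    @property
    def n_components(self) -> int:
        return len(self.variance_fractions)

    def scores_series(self, component: int) -> pd.Series:
        """Scores of one component (1-based) indexed by position."""
        return pd.Series(self.scores[:, component - 1], index=list(self.row_index))


def _normalize(x: np.ndarray, normalization: str) -> np.ndarray:
    if normalization == "per_position_z":
        sd = x.std(axis=1, ddof=0, keepdims=True)
        if np.any(sd == 0):
            raise ValueError("constant row: cannot z-score per position")
        return (x - x.mean(axis=1, keepdims=True)) / sd
    if normalization == "per_column_center":
        return x - x.mean(axis=0, keepdims=True)
    raise ValueError(f"unknown normalization {normalization!r}; one of {NORMALIZATIONS}")


def pca(matrix, normalization: str = "per_column_center") -> PCAResult:
    """Principal component analysis of a score matrix.

    Components come from the SVD of the normalized matrix (equivalently an
    eigen-decomposition of its covariance), ordered by decreasing variance
    fraction; fractions sum to 1 over all retained components.
    """
    if isinstance(matrix, pd.DataFrame):
        if matrix.isna().any().any():
            raise ValueError("matrix has missing values; impute first")
        row_index = tuple(matrix.index)
        columns = tuple(matrix.columns)
        x = matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(matrix, dtype=float)
        row_index = tuple(range(x.shape[0]))
        columns = tuple(range(x.shape[1]))
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("matrix must be 2-D with at least 2 rows and columns")
    z = _normalize(x, normalization)
    if np.allclose(z, 0.0):
        raise ValueError("matrix has zero variance after normalization")
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    keep = s > s[0] * 1e-12
    u, s, vt = u[:, keep], s[keep], vt[keep]
    signs = np.where(vt.sum(axis=1) >= 0, 1.0, -1.0)
    u = u * signs
    vt = vt * signs[:, None]
    var = s**2
    return PCAResult(
        scores=u * s,
        loadings=vt,
        variance_fractions=var / var.sum(),
        normalization=normalization,
        normalized=z,
        row_index=row_index,
        columns=columns,
    )


def frequency_matrix(
    msa,
    position_to_column: dict[int, int],
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Log amino-acid frequencies of the alignment columns mapped to
    library positions.

    ``position_to_column`` maps 1-based positions to 0-based alignment
    columns; unmapped positions raise with the offenders listed. Gaps are
    excluded from frequencies; ``pseudocount`` (default 1/(n_sequences+20))
    keeps zero-frequency entries finite under the log transform.
    """
    from .annotate import column_frequencies

    n_seq = len(msa)
    if pseudocount is None:
        pseudocount = 1.0 / (n_seq + 20)
    missing = [p for p, c in position_to_column.items() if c is None]
    if missing:
        raise ValueError(f"positions without alignment column: {sorted(missing)}")
    rows = {}
    for pos, col in sorted(position_to_column.items()):
        length = msa.get_alignment_length() if hasattr(msa, "get_alignment_length") else len(msa[0])
        if not 0 <= col < length:
            raise ValueError(f"position {pos} maps outside the alignment (column {col})")
        column = [str(rec.seq[col]) for rec in msa]
        rows[pos] = np.log(column_frequencies(column, pseudocount=pseudocount).to_numpy())
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(AA20))


def pc_feature_correlation(
    result: PCAResult, component: int, feature
) -> float | None:
    """Pearson R between one component's scores and a per-position feature.

    ``feature`` may be a Series indexed by position (pairwise-complete
    matching) or an array aligned with the score rows. Zero-variance
    features have no defined R and return None.
    """
    scores = result.scores_series(component)
    if isinstance(feature, pd.Series):
        feature = feature.reindex(scores.index)
    feat = np.asarray(feature, dtype=float)
    sc = scores.to_numpy(dtype=float)
    ok = np.isfinite(feat) & np.isfinite(sc)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 paired values")
    feat, sc = feat[ok], sc[ok]
    if np.ptp(feat) == 0 or np.ptp(sc) == 0:
        return None
    return float(np.corrcoef(sc, feat)[0, 1])


def pooled_feature_correlation(pairs: list[tuple[pd.Series, pd.Series]]) -> float:
    """Pearson R over score/feature pairs pooled across orthologues.

    Pooling can change conclusions relative to per-orthologue correlations
    (between-orthologue offsets enter the pooled R), so both views are
    worth reporting.
    """
    xs, ys = [], []
    for scores, feature in pairs:
        feature = feature.reindex(scores.index)
        ok = scores.notna() & feature.notna()
        xs.append(scores[ok].to_numpy(dtype=float))
        ys.append(feature[ok].to_numpy(dtype=float))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    return float(np.corrcoef(x, y)[0, 1])


def fourfold_average(
    values: pd.Series,
    positions: pd.DataFrame,
    second: pd.Series | None = None,
):
    """Average a per-position series over the four-fold symmetry quadrants.

    ``positions`` needs columns position, library, within_position. The
    result is a 20-point series indexed by four-fold offset, each the mean
    over the quadrants present at that offset (missing quadrants are
    averaged over what exists). With ``second`` given, returns
    ``(avg, avg_second, R)`` — the Pearson correlation between the two
    averaged series.
    """
    cells = {
        int(r.position): fourfold_index(int(r.library), int(r.within_position))
        for _, r in positions.iterrows()
    }

    def average(series: pd.Series) -> pd.Series:
        df = pd.DataFrame(
            {
                "offset": [cells[int(p)][1] for p in series.index],
                "value": series.to_numpy(dtype=float),
            }
        )
        return df.groupby("offset")["value"].mean()

    avg = average(values)
    if second is None:
        return avg
    avg2 = average(second)
    shared = avg.index.intersection(avg2.index)
    r = float(np.corrcoef(avg.loc[shared], avg2.loc[shared])[0, 1])
    return avg, avg2, r
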