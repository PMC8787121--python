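"""Subjective-score arithmetic: outlier screening, differential scores, DMOS.

A rating matrix holds subject-by-image scores on a continuous [1, 5]
scale with NaN as the missing-value marker. DMOS for a distorted image is
the mean over retained subjects of (reference score - distorted score),
so larger DMOS means worse quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_fixtures import ValidationError


@dataclass
class RatingMatrix:
    """Subject x image score grid on [1, 5] with NaN for missing.

    ``ref_of`` maps each distorted image id to its reference image id; it
    is empty for a matrix of reference-image ratings. ``outlier_mask`` is
    an optional bookkeeping grid set by :func:`simulate_ratings` marking
    planted outliers (test plumbing, never consulted by the arithmetic).
    """

    scores: np.ndarray
    subject_ids: list[str]
    image_ids: list[str]
    ref_of: dict[str, str] = field(default_factory=dict)
    outlier_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.ndim != 2:
            raise ValidationError("scores must be a 2-D subject x image grid")
        if self.scores.shape != (len(self.subject_ids), len(self.image_ids)):
            raise ValidationError("score grid must match the label lists")
        present = self.scores[~np.isnan(self.scores)]
        if present.size and (present.min() < 1 or present.max() > 5):
            raise ValidationError("non-missing scores must lie in [1, 5]")

    def column(self, image_id: str) -> np.ndarray:
        return self.scores[:, self.image_ids.index(image_id)]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.scores, index=self.subject_ids, columns=self.image_ids)
        df.index.name = "subject_id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, ref_of: dict[str, str] | None = None) -> "RatingMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(
            scores=df.to_numpy(dtype=np.float64),
            subject_ids=[str(s) for s in df.index],
            image_ids=[str(c) for c in df.columns],
            ref_of=dict(ref_of or {}),
        )


@dataclass
class DMOSRecord:
    image_id: str
    dmos: float
    n_retained: int

    def __post_init__(self) -> None:
        if self.n_retained < 1:
            raise ValidationError("n_retained must be >= 1")
        if not np.isfinite(self.dmos):
            raise ValidationError("dmos must be finite")


def screen_outliers(ratings: RatingMatrix, k: float = 2.0,
                    passes: int | None = 1) -> RatingMatrix:
    """Mark scores missing when farther than k sample standard deviations
    from their image's mean score.

    Each pass over an image column: with the column's non-missing mean m
    and sample sd s (ddof=1), a score x is dropped when |x - m| > k*s.
    Columns with zero sd retain everything. An image losing all its
    scores is an error. The default is a single pass (the published
    per-score screening); ``passes=None`` repeats until a fixed point,
    which makes the operator idempotent.
    """
    if not (k > 0):
        raise ValidationError("k must be positive")
    if passes is not None and passes < 1:
        raise ValidationError("passes must be >= 1 or None")
    scores = ratings.scores.copy()
    for j, image_id in enumerate(ratings.image_ids):
        col = scores[:, j]
        present = ~np.isnan(col)
        if present.sum() < 2:
            raise ValidationError(
                f"image {image_id!r} needs at least 2 subjects for screening"
            )
        remaining = passes
        while remaining is None or remaining > 0:
            present = ~np.isnan(col)
            vals = col[present]
            sd = vals.std(ddof=1) if vals.size > 1 else 0.0
            if sd == 0:
                break
            drop = present & (np.abs(col - vals.mean()) > k * sd)
            col[drop] = np.nan
            if np.isnan(col).all():
                raise ValidationError(
                    f"screening removed every score of image {image_id!r}"
                )
            if remaining is not None:
                remaining -= 1
            elif not drop.any():
                break
    return RatingMatrix(
        scores=scores,
        subject_ids=list(ratings.subject_ids),
        image_ids=list(ratings.image_ids),
        ref_of=dict(ratings.ref_of),
        outlier_mask=None if ratings.outlier_mask is None else ratings.outlier_mask.copy(),
    )


def compute_dmos(
    ratings: RatingMatrix,
    reference_scores: RatingMatrix,
    k: float = 2.0,
) -> list[DMOSRecord]:
    """Screen both matrices, difference per retained subject, then average.

    For distorted image b and subject a, D_ab = x_ab - x'_ab where x_ab is
    the subject's score of b's reference image and x'_ab the score of b
    itself; a subject contributes only when both scores survive screening.
    Records come back in the input image order.
    """
    if set(ratings.subject_ids) != set(reference_scores.subject_ids):
        raise ValidationError("distorted and reference matrices must share subjects")
    if len(ratings.subject_ids) >= 2:
        screened = screen_outliers(ratings, k)
        screened_ref = screen_outliers(reference_scores, k)
    else:  # screening needs >= 2 subjects; a lone subject is kept as-is
        screened, screened_ref = ratings, reference_scores
    # align reference rows to the distorted matrix's subject order
    order = [screened_ref.subject_ids.index(s) for s in screened.subject_ids]
    ref_scores = screened_ref.scores[order, :]

    records: list[DMOSRecord] = []
    for j, image_id in enumerate(screened.image_ids):
        ref_id = screened.ref_of.get(image_id)
        if ref_id is None or ref_id not in screened_ref.image_ids:
            raise ValidationError(f"no reference rating column for image {image_id!r}")
        rj = screened_ref.image_ids.index(ref_id)
        d = ref_scores[:, rj] - screened.scores[:, j]
        d = d[~np.isnan(d)]
        if d.size == 0:
            raise ValidationError(f"no retained subject pairs for image {image_id!r}")
        records.append(DMOSRecord(image_id=image_id, dmos=float(d.mean()),
                                  n_retained=int(d.size)))
    return records


def simulate_ratings(
    true_quality,
    n_subjects: int = 16,
    subject_bias_sd: float = 0.2,
    noise_sd: float = 0.2,
    outlier_rate: float = 0.0,
    seed: int = 0,
    ref_of: dict[str, str] | None = None,
    image_ids: list[str] | None = None,
) -> tuple[RatingMatrix, RatingMatrix]:
    """Seeded rating-experiment simulator.

    Each true quality q in [0, 1] maps to a latent opinion 1 + 4q; every
    subject adds a Normal(0, subject_bias_sd) bias and each score gets
    Normal(0, noise_sd) noise; a Bernoulli(outlier_rate) subset of the
    distorted scores is replaced by Uniform[1, 5] draws (positions kept in
    ``outlier_mask``); everything is clipped to [1, 5]. Reference images
    are rated as true quality 1. Deterministic per seed.
    """
    q = np.asarray(list(true_quality), dtype=np.float64)
    if q.ndim != 1 or q.size == 0:
        raise ValidationError("true_quality must be a nonempty 1-D list")
    if q.min() < 0 or q.max() > 1:
        raise ValidationError("true quality values must lie in [0, 1]")
    if n_subjects < 2:
        raise ValidationError("need at least 2 subjects")
    if not (0 <= outlier_rate <= 1):
        raise ValidationError("outlier_rate must lie in [0, 1]")

    n_img = q.size
    if image_ids is None:
        image_ids = [f"img_{i:04d}" for i in range(n_img)]
    if ref_of is None:
        ref_of = {img: f"ref_{i:04d}" for i, img in enumerate(image_ids)}
    ref_ids = sorted(set(ref_of[img] for img in image_ids))

    rng = np.random.default_rng(seed)
    bias = rng.normal(0.0, subject_bias_sd, size=n_subjects)[:, None]

    latent = 1.0 + 4.0 * q[None, :]
    dist = latent + bias + rng.normal(0.0, noise_sd, size=(n_subjects, n_img))
    mask = rng.random(size=(n_subjects, n_img)) < outlier_rate
    dist[mask] = rng.uniform(1.0, 5.0, size=int(mask.sum()))
    dist = np.clip(dist, 1.0, 5.0)

    ref = 5.0 + bias + rng.normal(0.0, noise_sd, size=(n_subjects, len(ref_ids)))
    ref = np.clip(ref, 1.0, 5.0)

    subjects = [f"subj_{a:02d}" for a in range(n_subjects)]
    distorted = RatingMatrix(scores=dist, subject_ids=subjects,
                             image_ids=list(image_ids), ref_of=dict(ref_of),
                             outlier_mask=mask)
    reference = RatingMatrix(scores=ref, subject_ids=subjects, image_ids=ref_ids)
    return distorted, reference


def dmos_records_to_frame(records: list[DMOSRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.image_id, r.dmos, r.n_retained) for r in records],
        columns=["image_id", "dmos", "n_retained"],
    )
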