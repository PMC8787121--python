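"""End-to-end score: saliency-weighted pooling of fused feature similarities.

The final quality score pools, over the whole image domain, the fused
local term ``[P_s + w1 * P_l * P_c]^theta`` times the saliency-contour
similarity ``Con^psi``, weighted by the positional saliency map, and is
normalized by the attainable maximum ``(1 + w1)^theta`` so identical
images score exactly 1.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .features import SimilarityMap, WindowSpec, local_mean_map, local_std_map, \
    scharr_gradient_magnitude, similarity_map
from .io_fixtures import DistortionSet, ImagePlane, ValidationError
from .saliency import SaliencyParams, spectral_residual_saliency, positional_weight_map

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MMIQAParams:
    """Every free constant of the metric.

    Stabilizers follow the SSIM/GMS conventions: C1 = 1e-4 for maps on
    [0, 1] (saliency), C2 = (0.01*255)^2 for luminance, C3 = (0.03*255)^2
    for contrast, C4 = 170 for gradients. ``w1`` weights the
    luminance-contrast product against the gradient term; ``theta`` and
    ``psi`` are the local-term and global-structure importance exponents.
    """

    c1: float = 1e-4
    c2: float = (0.01 * 255.0) ** 2
    c3: float = (0.03 * 255.0) ** 2
    c4: float = 170.0
    w1: float = 0.6
    theta: float = 1.0
    # psi = 1 lets the jumpy saliency-contour term override the monotone
    # feature terms on JPEG ladders; 0.5 keeps rankings stable
    psi: float = 0.5
    pooling_epsilon: float = 1e-12
    saliency: SaliencyParams = field(default_factory=SaliencyParams)
    window: WindowSpec = field(default_factory=WindowSpec)

    def __post_init__(self) -> None:
        for name in ("c1", "c2", "c3", "c4", "theta", "pooling_epsilon"):
            if not (getattr(self, name) > 0):
                raise ValidationError(f"{name} must be strictly positive")
        # psi = 0 is admitted as a diagnostic degenerate mode (Con term off)
        if self.psi < 0 or self.w1 < 0:
            raise ValidationError("w1 and psi must be nonnegative")

    # --- flat config (de)serialization -------------------------------------
    _FLAT_KEYS = (
        "c1", "c2", "c3", "c4", "w1", "theta", "psi", "pooling_epsilon",
        "working_width", "gamma", "residual_filter_size", "smooth_sigma",
        "log_epsilon", "stretch_domain",
        "window_kind", "window_size", "window_sigma",
    )

    def to_flat_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("c1", "c2", "c3", "c4", "w1", "theta", "psi", "pooling_epsilon")}
        for k in ("working_width", "gamma", "residual_filter_size",
                  "smooth_sigma", "log_epsilon", "stretch_domain"):
            d[k] = getattr(self.saliency, k)
        d["window_kind"] = self.window.kind
        d["window_size"] = self.window.size
        d["window_sigma"] = self.window.sigma
        return d

    @classmethod
    def from_flat_dict(cls, d: dict) -> "MMIQAParams":
        unknown = sorted(set(d) - set(cls._FLAT_KEYS))
        if unknown:
            raise ValidationError(f"unknown config keys: {unknown}")
        base = cls()
        flat = base.to_flat_dict()
        flat.update(d)
        sal = SaliencyParams(
            working_width=int(flat["working_width"]),
            gamma=float(flat["gamma"]),
            residual_filter_size=int(flat["residual_filter_size"]),
            smooth_sigma=float(flat["smooth_sigma"]),
            log_epsilon=float(flat["log_epsilon"]),
            stretch_domain=str(flat["stretch_domain"]),
        )
        win = WindowSpec(
            kind=str(flat["window_kind"]),
            size=int(flat["window_size"]),
            sigma=float(flat["window_sigma"]),
        )
        return cls(
            c1=float(flat["c1"]), c2=float(flat["c2"]), c3=float(flat["c3"]),
            c4=float(flat["c4"]), w1=float(flat["w1"]),
            theta=float(flat["theta"]), psi=float(flat["psi"]),
            pooling_epsilon=float(flat["pooling_epsilon"]),
            saliency=sal, window=win,
        )

    @classmethod
    def from_yaml(cls, path) -> "MMIQAParams":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ValidationError("config file must be a flat key: value mapping")
        return cls.from_flat_dict(d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_flat_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        payload = json.dumps(self.to_flat_dict(), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class QualityScore:
    value: float
    reference_id: str = ""
    distorted_id: str = ""
    params_digest: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.value <= 1 + 1e-12):
            raise ValidationError(f"score {self.value} outside (0, 1]")
        self.value = min(float(self.value), 1.0)


def global_structure(con, weights: np.ndarray, psi: float,
                     pooling_epsilon: float = 1e-12) -> float:
    """Weighted mean of ``con**psi`` over the whole domain."""
    values = con.values if isinstance(con, SimilarityMap) else np.asarray(con, float)
    weights = np.asarray(weights, dtype=np.float64)
    if values.shape != weights.shape:
        raise ValidationError("con and weights must share dimensions")
    if psi < 0:
        raise ValidationError("psi must be nonnegative")
    wsum = weights.sum()
    if wsum <= pooling_epsilon:
        logger.warning("all-zero pooling weights; falling back to unweighted mean")
        return float((values**psi).mean())
    return float((values**psi * weights).sum() / wsum)


def mm_iqa_score(
    reference: ImagePlane,
    distorted: ImagePlane,
    params: MMIQAParams | None = None,
    *,
    reference_id: str = "",
    distorted_id: str = "",
    weight_map: np.ndarray | None = None,
    return_terms: bool = False,
):
    """Full-reference quality of ``distorted`` against ``reference``.

    Saliency maps of both planes give the contour-similarity map (large
    scale) and the positional pooling weights; luminance, contrast and
    Scharr-gradient similarity maps (native scale) form the fused local
    term. ``weight_map`` overrides the positional weights (diagnostic use,
    e.g. uniform pooling). Returns a :class:`QualityScore`; with
    ``return_terms=True`` also a dict of per-term means.
    """
    if params is None:
        params = MMIQAParams()
    if (reference.height, reference.width) != (distorted.height, distorted.width):
        raise ValidationError("reference and distorted dimensions must match")

    sal_r = spectral_residual_saliency(reference, params.saliency)
    sal_d = spectral_residual_saliency(distorted, params.saliency)
    con = similarity_map(sal_r.values, sal_d.values, params.c1).values
    if weight_map is None:
        wmap = positional_weight_map(sal_r, sal_d, params.saliency.smooth_sigma)
    else:
        wmap = np.asarray(weight_map, dtype=np.float64)
        if wmap.shape != con.shape:
            raise ValidationError("weight_map dimensions must match the image")

    p_l = similarity_map(
        local_mean_map(reference, params.window),
        local_mean_map(distorted, params.window), params.c2).values
    p_c = similarity_map(
        local_std_map(reference, params.window),
        local_std_map(distorted, params.window), params.c3).values
    p_s = similarity_map(
        scharr_gradient_magnitude(reference),
        scharr_gradient_magnitude(distorted), params.c4).values

    local = (p_s + params.w1 * p_l * p_c) ** params.theta * con ** params.psi
    if not np.all(np.isfinite(local)):
        raise ArithmeticError("non-finite values in the fused local term")

    wsum = wmap.sum()
    if wsum <= params.pooling_epsilon:
        logger.warning("all-zero pooling weights; using uniform pooling")
        pooled = float(local.mean())
    else:
        pooled = float((local * wmap).sum() / wsum)
    value = pooled / (1.0 + params.w1) ** params.theta

    score = QualityScore(
        value=value, reference_id=reference_id, distorted_id=distorted_id,
        params_digest=params.digest(),
    )
    if return_terms:
        terms = {
            "p_l_mean": float(p_l.mean()),
            "p_c_mean": float(p_c.mean()),
            "p_s_mean": float(p_s.mean()),
            "con_mean": float(con.mean()),
            "global_structure": global_structure(con, wmap, params.psi,
                                                 params.pooling_epsilon),
        }
        return score, terms
    return score


def mm_iqa_batch(sets: Sequence[DistortionSet], params: MMIQAParams | None = None) -> pd.DataFrame:
    """Score every (reference, level) pair; failures become error rows.

    Rows are ordered by input set then level (stable). Columns:
    reference_id, level, score, params_digest, error.
    """
    if len(sets) == 0:
        raise ValidationError("batch requires a nonempty list of distortion sets")
    if params is None:
        params = MMIQAParams()
    digest = params.digest()
    rows = []
    for ds in sets:
        for level, plane in zip(ds.levels, ds.distorted):
            try:
                s = mm_iqa_score(ds.reference, plane, params,
                                 reference_id=ds.reference_id,
                                 distorted_id=f"{ds.reference_id}:q{level}")
                rows.append((ds.reference_id, level, s.value, digest, ""))
            except Exception as exc:  # noqa: BLE001 - batch must continue
                logger.error("scoring failed for %s level %s: %s",
                             ds.reference_id, level, exc)
                rows.append((ds.reference_id, level, np.nan, digest, str(exc)))
    return pd.DataFrame(rows, columns=["reference_id", "level", "score",
                                       "params_digest", "error"])
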