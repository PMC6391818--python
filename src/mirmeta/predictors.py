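"""Base-predictor specifications and score scaling.

Four sequence-based miRNA target predictors feed the meta-predictor:
miRanda, miRDB, PITA and TargetScan.  Each emits scores on its own native
scale; all are mapped onto a common [-1, 1] axis on which *lower* scores
indicate a stronger (more likely true) interaction.  miRDB is the one
predictor whose native scores are high-is-good, so it is negated before
the affine map.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "PredictorSpec",
    "PREDICTORS",
    "PREDICTOR_ORDER",
    "scale_score",
    "unscale_score",
    "scaled_default_cutoff",
]


@dataclass(frozen=True)
class PredictorSpec:
    """One base predictor: native score range, default cutoff, orientation.

    Attributes
    ----------
    id : str
        Canonical lower-case name.
    native_range : tuple of float
        (low, high) of the scores the predictor publishes.
    default_cutoff : float
        The predictor's own true-prediction cutoff on its native scale.
    invert : bool
        True when high native scores mean a stronger interaction
        (miRDB); such scores are negated before scaling so that low
        always means strong on the common axis.
    """

    id: str
    native_range: tuple[float, float]
    default_cutoff: float
    invert: bool = False

    def __post_init__(self) -> None:
        low, high = self.native_range
        if not low < high:
            raise ValueError(
                f"{self.id}: degenerate native range {self.native_range!r}"
            )


#: Canonical predictor order used everywhere (feature vectors, subset keys).
PREDICTOR_ORDER: tuple[str, ...] = ("miranda", "mirdb", "pita", "targetscan")

PREDICTORS: dict[str, PredictorSpec] = {
    "miranda": PredictorSpec("miranda", (-1.364, -0.1), -1.0),
    "mirdb": PredictorSpec("mirdb", (50.0, 100.0), 80.0, invert=True),
    "pita": PredictorSpec("pita", (-43.24, 21.4), -10.0),
    "targetscan": PredictorSpec("targetscan", (-9.05, 0.0), -0.36),
}


def scale_score(predictor: PredictorSpec | str, raw: float) -> float:
    """Map a raw predictor score onto the common [-1, 1] axis.

    The map is affine from the native range onto (-1, 1); for inverted
    predictors the raw score is negated and the range mirrored first.
    Out-of-range raw scores (real dumps exceed the published ranges) are
    clamped to [-1, 1] after mapping.
    """
    spec = PREDICTORS[predictor] if isinstance(predictor, str) else predictor
    low, high = spec.native_range
    x = raw
    if spec.invert:
        x = -x
        low, high = -high, -low
    scaled = 2.0 * (x - low) / (high - low) - 1.0
    return min(1.0, max(-1.0, scaled))


def unscale_score(predictor: PredictorSpec | str, scaled: float) -> float:
    """Inverse of :func:`scale_score` for in-range values."""
    spec = PREDICTORS[predictor] if isinstance(predictor, str) else predictor
    low, high = spec.native_range
    if spec.invert:
        low, high = -high, -low
    x = (scaled + 1.0) / 2.0 * (high - low) + low
    return -x if spec.invert else x


def scaled_default_cutoff(predictor: PredictorSpec | str) -> float:
    """A predictor's own true-prediction cutoff on the common axis.

    Calls below this value are "true" under the predictor's default
    settings: -0.424 (miRanda), -0.2 (miRDB), 0.028 (PITA),
    0.920 (TargetScan).
    """
    spec = PREDICTORS[predictor] if isinstance(predictor, str) else predictor
    return scale_score(spec, spec.default_cutoff)
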