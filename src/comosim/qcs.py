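"""Quadratic-constant spline (QCS) basis.

The mortality model uses covariate transforms that are a half parabola to
the left of a cut point and constant beyond it.  A one-unit rise in a
comorbidity index matters far more at low index levels than at high ones,
and the comorbidity effect on mortality fades out at extreme old age; the
QCS captures both with a single fixed cut point per covariate.

We use the minimal one-parameter form

    g(x; c) = (min(x, c) - c)^2

which is a second-degree polynomial with its extremum at the cut point
``c``, joins the constant branch with a continuous first derivative, and is
identically zero for ``x >= c``.  Any vertical scale or offset is absorbed
by the GLM coefficient multiplying the basis.

Sign convention: g is *decreasing* in x below the cut point, so a covariate
whose higher values raise mortality carries a **negative** fitted weight on
its QCS basis value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = ["QCSSpec", "qcs_value"]


@dataclass(frozen=True)
class QCSSpec:
    """A QCS basis specification: just the cut point, in covariate units."""

    cut_point: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.cut_point):
            raise ValidationError("QCS cut point must be finite")


def qcs_value(x, spec):
    """Evaluate the QCS basis g(x; c) = (min(x, c) - c)^2.

    Parameters
    ----------
    x : scalar or array-like
        Covariate value(s); must be finite.
    spec : QCSSpec or float
        The cut point ``c`` (or a :class:`QCSSpec` carrying it).

    Returns
    -------
    Scalar or ndarray with the same shape as ``x``.
    """
    c = spec.cut_point if isinstance(spec, QCSSpec) else float(spec)
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("QCS input must be finite")
    out = (np.minimum(arr, c) - c) ** 2
    if np.isscalar(x) or arr.ndim == 0:
        return float(out)
    return out
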