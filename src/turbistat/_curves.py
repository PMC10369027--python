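"""Four-parameter logistic family shared by the virtual optics and the calibration fit.

The raw light-scattering signal of a smart sleeve is modelled as a monotone,
saturating function of culture optical density:

    raw = a + b / (1 + exp((od - c) / d))

with ``d > 0``.  The sign of ``b`` sets the direction (``b > 0``: raw decreases
with OD).  Downstream code relies only on monotonicity, never on the sign.
"""

from __future__ import annotations

import numpy as np

__all__ = ["logistic4", "logistic4_inverse", "logistic4_deriv", "raw_domain"]


def logistic4(od, a: float, b: float, c: float, d: float):
    """Raw scattering value as a function of OD."""
    od = np.asarray(od, dtype=float)
    out = a + b / (1.0 + np.exp((od - c) / d))
    return out if out.ndim else float(out)


def logistic4_inverse(raw, a: float, b: float, c: float, d: float):
    """OD as a function of raw scattering: the analytic inverse of :func:`logistic4`.

    od = c + d * ln(b / (raw - a) - 1)

    Only defined for raw strictly between the asymptotes ``a`` and ``a + b``.
    """
    raw = np.asarray(raw, dtype=float)
    ratio = b / (raw - a) - 1.0
    if np.any(ratio <= 0.0):
        raise ValueError(
            "raw value outside the invertible range of the calibration curve "
            f"(asymptotes {min(a, a + b):.1f}..{max(a, a + b):.1f})"
        )
    out = c + d * np.log(ratio)
    return out if out.ndim else float(out)


def logistic4_deriv(od, a: float, b: float, c: float, d: float):
    """d(raw)/d(OD); sign is -sign(b) for d > 0, magnitude peaks at od = c."""
    od = np.asarray(od, dtype=float)
    # exp(u)/(1+exp(u))^2 written as 1/(4 cosh^2(u/2)) for overflow safety
    u = (od - c) / d
    out = -(b / d) * 0.25 / np.cosh(u / 2.0) ** 2
    return out if out.ndim else float(out)


def raw_domain(a: float, b: float) -> tuple[float, float]:
    """Open interval of raw values for which the inverse map exists."""
    return (min(a, a + b), max(a, a + b))
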