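"""Helpers for the 180-degree-periodic orientation domain.

An orientation (the axis of an elongated stimulus, or the principal axis of
a covariance matrix) has period 180 deg: rotating by 180 deg yields the same
axis.  All angles are in degrees, measured counterclockwise from the
horizontal +x axis with the y axis pointing up.
"""

from __future__ import annotations

import numpy as np

__all__ = ["wrap_orientation", "wrap_bias", "canonical_orientation"]


def _scalarize(value, template):
    if np.ndim(template) == 0:
        return float(value)
    return value


def wrap_orientation(theta):
    """Reduce an angle to the orientation domain [0, 180)."""
    return _scalarize(np.mod(np.asarray(theta, dtype=float), 180.0), theta)


def wrap_bias(delta):
    """Map an orientation difference to the signed interval (-90, 90].

    A tie at exactly +/-90 deg maps to +90 so that the periodic interval has
    exactly one closed endpoint.  Positive values are counterclockwise.
    """
    d = np.mod(np.asarray(delta, dtype=float), 180.0)
    d = np.where(d > 90.0, d - 180.0, d)
    return _scalarize(d, delta)


def canonical_orientation(theta):
    """Fold an orientation onto its mirror pair's canonical member.

    Orientations theta and 180 - theta are mirror images across the vertical
    axis.  The canonical member lies in [0, 90]; the returned sign is -1 when
    the input was the mirrored member (theta > 90), since reflecting a
    stimulus across the vertical axis flips the sign of its orientation bias.

    Returns
    -------
    (canonical, sign) with canonical in [0, 90] and sign in {+1, -1}.
    """
    t = np.mod(np.asarray(theta, dtype=float), 180.0)
    mirrored = t > 90.0
    canon = np.where(mirrored, 180.0 - t, t)
    sign = np.where(mirrored, -1.0, 1.0)
    return _scalarize(canon, theta), _scalarize(sign, theta)
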