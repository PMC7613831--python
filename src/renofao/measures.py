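"""Closed-form morphometric and quantification formulas for study endpoints.

Covers stereological glomerular volume (Weibel-Gomez), podocyte foot-process
metrics measured on transmission electron micrographs, mitochondrial shape
descriptors, longitudinal percentage-delta changes, and qRT-PCR relative
quantification by the comparative-Ct (delta-delta-Ct) method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

# Weibel-Gomez stereology constants: beta for spheres, d a size-distribution
# correction; config-exposed because they come from the stereology literature,
# not from any single study.
WEIBEL_GOMEZ_BETA = 1.38
WEIBEL_GOMEZ_D = 1.01

#: GBM window over which podocyte foot processes are counted, in micrometres.
GBM_WINDOW_UM = 8.0


def glomerular_volume(area, beta: float = WEIBEL_GOMEZ_BETA, d: float = WEIBEL_GOMEZ_D):
    """Glomerular tuft volume (um^3) from mean profile area (um^2).

    V = (beta / d) * A^(3/2), the Weibel-Gomez estimator for spherical
    particles sampled by random planes.
    """
    area = np.asarray(area, dtype=float)
    if np.any(area < 0):
        raise ValueError("glomerular area must be nonnegative")
    out = (beta / d) * np.power(area, 1.5)
    return out.item() if out.ndim == 0 else out


def roundness(area, major_axis):
    """Object roundness 4*A / (pi * L^2) with L the major axis.

    For an ellipse with semi-axes a >= b this equals b/a, i.e. the inverse of
    the aspect ratio, so roundness is 1 for a circle and decreases as the
    object elongates.
    """
    area = np.asarray(area, dtype=float)
    major_axis = np.asarray(major_axis, dtype=float)
    if np.any(major_axis <= 0):
        raise ValueError("major axis must be positive")
    out = 4.0 * area / (np.pi * major_axis**2)
    return out.item() if out.ndim == 0 else out


def aspect_ratio(major_axis, minor_axis):
    """Major-axis / minor-axis length ratio (>= 1 for valid measurements)."""
    major_axis = np.asarray(major_axis, dtype=float)
    minor_axis = np.asarray(minor_axis, dtype=float)
    if np.any(minor_axis <= 0):
        raise ValueError("minor axis must be positive")
    out = major_axis / minor_axis
    return out.item() if out.ndim == 0 else out


def pfpd_from_pfpf(pfpf):
    """Podocyte foot-process diameter (nm) from foot-process frequency.

    PFPF is counted per 8 um of glomerular basement membrane, so the mean
    diameter is 8000 nm / PFPF.
    """
    pfpf = np.asarray(pfpf, dtype=float)
    if np.any(pfpf <= 0):
        raise ValueError("PFPF must be positive")
    out = GBM_WINDOW_UM * 1000.0 / pfpf
    return out.item() if out.ndim == 0 else out


def delta_percent(pre, post):
    """Percentage change 100 * (post - pre) / pre, per animal."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if np.any(pre == 0):
        raise ValueError("pre-intervention value must be nonzero")
    out = 100.0 * (post - pre) / pre
    return out.item() if out.ndim == 0 else out


@dataclass(frozen=True)
class CtRecord:
    """One qRT-PCR measurement: threshold cycles for target and reference gene."""

    sample_id: str
    group: str
    target_ct: float
    reference_ct: float


def relative_quantification_ddct(
    records: list[CtRecord] | pd.DataFrame, calibrator_group: str
) -> pd.DataFrame:
    """Relative quantification by the comparative-Ct method.

    dCt = target Ct - reference Ct per sample; ddCt subtracts the calibrator
    group's mean dCt; RQ = 2^(-ddCt). The calibrator group therefore has
    geometric-mean RQ of exactly 1.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([r.__dict__ for r in records])
    if not np.isfinite(df[["target_ct", "reference_ct"]].to_numpy()).all():
        raise ValueError("Ct values must be finite")
    cal = df["group"] == calibrator_group
    if not cal.any():
        raise ValueError(f"calibrator group {calibrator_group!r} has no samples")
    df["dct"] = df["target_ct"] - df["reference_ct"]
    df["ddct"] = df["dct"] - df.loc[cal, "dct"].mean()
    df["rq"] = np.power(2.0, -df["ddct"])
    return df
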