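"""Radial-vs-triaxial SNIR trade-off under interference projection.

With no interference the signal-to-noise ratio is ``SNR = signal /
sigma_sensor``.  Modelling the interference standard deviation as ``a``
times the sensor noise, projecting out an interference topography
attenuates the brain signal by an amplitude factor ``Att`` in [0, 1] and
shields the interference by a linear factor ``SF``, giving the
signal-to-noise-in-interference ratio::

    SNIR = SNR * Att / sqrt(1 + (a / SF)**2)

A radial-only array has a lower white-noise floor than a triaxial one by a
factor ``w`` (default 2.5), which raises both its SNR and its
interference-to-noise ratio.  Taking the ratio of two such expressions::

    SNIR_rad / SNIR_tri
        = w * (Att_rad / Att_tri) * sqrt(SF**2 + a_tri**2)
                                  / sqrt(SF**2 + w**2 * a_tri**2)

Values above 1 favour the radial array: low interference or very high
shielding factors favour radial sensing, while strong or spatially complex
interference (which forces larger ``Att_rad``) favours triaxial sensing.

Shielding factors given in dB use the amplitude convention
``SF = 10**(dB/20)``, matching the division of the interference amplitude
by ``SF``; attenuation factors derived from dB variance losses likewise use
``Att = 10**(-loss_dB/20)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from opmarray.exceptions import InvalidParameterError, UndefinedRatioError

__all__ = ["SNIRParams", "SNIRGrid", "snir", "snir_ratio", "snir_grid",
           "db_to_linear_amplitude", "attenuation_db_to_factor"]

DEFAULT_W = 2.5


def db_to_linear_amplitude(db) -> np.ndarray:
    """Amplitude-convention dB to linear: ``10**(db/20)``."""
    return np.power(10.0, np.asarray(db, float) / 20.0)


def attenuation_db_to_factor(loss_db) -> np.ndarray:
    """Positive dB variance loss to an amplitude attenuation factor in [0, 1]."""
    return np.power(10.0, -np.asarray(loss_db, float) / 20.0)


@dataclass
class SNIRParams:
    """Parameters of the radial/triaxial SNIR comparison (all dimensionless)."""

    w: float = DEFAULT_W        # radial white-noise advantage (> 0)
    a_tri: float = 0.0          # interference / sensor noise, triaxial (>= 0)
    sf: float = 1.0             # linear shielding factor (>= 1)
    att_rad: float = 1.0        # amplitude attenuation factors in [0, 1]
    att_tri: float = 1.0

    def __post_init__(self):
        if self.w <= 0 or self.a_tri < 0 or self.sf < 1:
            raise InvalidParameterError("need w > 0, a_tri >= 0, sf >= 1")
        for att in (self.att_rad, self.att_tri):
            if not (0.0 <= att <= 1.0):
                raise InvalidParameterError("attenuation factors must lie in [0, 1]")


@dataclass
class SNIRGrid:
    """Radial/triaxial SNIR ratio over a (shielding, interference) grid."""

    sf_axis_db: np.ndarray
    a_axis: np.ndarray
    ratio: np.ndarray           # (len(a_axis), len(sf_axis_db))
    winner_mask: np.ndarray     # True where the radial array wins (ratio > 1)
    order: int | None = None
    meta: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd
        sf, a = np.meshgrid(self.sf_axis_db, self.a_axis)
        return pd.DataFrame(dict(sf_db=sf.ravel(), a=a.ravel(),
                                 ratio=self.ratio.ravel(),
                                 winner=np.where(self.winner_mask.ravel(),
                                                 "radial", "triaxial")))


def snir(signal, sigma_sensor, a, att, sf):
    """SNIR after projecting an interference topography.

    ``SNR * att / sqrt(1 + (a/sf)**2)`` with ``SNR = signal/sigma_sensor``.
    """
    sigma_sensor = np.asarray(sigma_sensor, float)
    sf = np.asarray(sf, float)
    if np.any(sigma_sensor <= 0) or np.any(sf < 1):
        raise InvalidParameterError("need sigma_sensor > 0 and sf >= 1")
    att = np.asarray(att, float)
    if np.any((att < 0) | (att > 1)):
        raise InvalidParameterError("att must lie in [0, 1]")
    snr = np.asarray(signal, float) / sigma_sensor
    return snr * att / np.sqrt(1.0 + (np.asarray(a, float) / sf) ** 2)


def snir_ratio(params: SNIRParams):
    """Closed-form ``SNIR_rad / SNIR_tri``; > 1 means the radial array wins."""
    if params.att_tri == 0.0:
        raise UndefinedRatioError("triaxial attenuation factor is zero")
    w, a, sf = params.w, params.a_tri, params.sf
    return (w * params.att_rad / params.att_tri
            * np.sqrt(sf ** 2 + a ** 2) / np.sqrt(sf ** 2 + w ** 2 * a ** 2))


def snir_grid(w=DEFAULT_W, sf_range_db=(1.0, 40.0), a_range=(0.0, 20.0),
              att_rad=1.0, att_tri=1.0, n_sf: int = 80, n_a: int = 81,
              order: int | None = None) -> SNIRGrid:
    """Evaluate the radial/triaxial SNIR ratio over a parameter grid.

    ``att_rad``/``att_tri`` are amplitude attenuation factors, typically
    converted from the lead-field attenuation sweep at a stated external
    order via :func:`attenuation_db_to_factor`.
    """
    if att_tri == 0.0:
        raise UndefinedRatioError("triaxial attenuation factor is zero")
    sf_db = np.linspace(*sf_range_db, n_sf)
    a = np.linspace(*a_range, n_a)
    sf = db_to_linear_amplitude(sf_db)[None, :]
    aa = a[:, None]
    ratio = (w * att_rad / att_tri
             * np.sqrt(sf ** 2 + aa ** 2) / np.sqrt(sf ** 2 + w ** 2 * aa ** 2))
    return SNIRGrid(sf_db, a, ratio, ratio > 1.0, order=order,
                    meta=dict(w=w, att_rad=att_rad, att_tri=att_tri))
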