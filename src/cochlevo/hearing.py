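"""Trait-calibrated prediction of hearing limits and echolocation call frequencies.

Two kinds of calibration link cochlear gross morphology to function:

* **Call-frequency models** — multiple regressions of log10 call frequency
  (minimum, peak-energy, maximum; kHz) on log10 *absolute* basilar-membrane
  length (mm) and log10 number of turns, fitted across laryngeal
  echolocators.  Two published coefficient sets ship as built-in model files
  (``davies2013_phylo``, the phylogenetically corrected set, and
  ``davies2013_ols``).
* **Audiogram calibrations** — four OLS regressions fitted to an audiogram
  table: high-frequency hearing limits (30 and 60 dB) on log10 relative
  membrane length, and low-frequency limits on the product
  log10(membrane length) x turns.

Evaluating either at reconstructed ancestral morphology yields the inferred
hearing/call capabilities of ancestral taxa.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from . import allometry
from .exceptions import DomainError
from .morphometry import relative_membrane_length

__all__ = [
    "CallFreqModel",
    "load_builtin_model",
    "predict_call_frequencies",
    "HearingCalibration",
    "fit_hearing_calibration",
    "predict_hearing_limits",
]

CALL_PARAMETERS = ("min", "peak", "max")
LIMIT_KEYS = ("hf30", "hf60", "lf30", "lf60")


@dataclass(frozen=True)
class CallFreqModel:
    """Per call parameter (min/peak/max): intercept plus coefficients on
    log10 membrane length (mm) and log10 turns.  ``provenance`` tags where
    the coefficients came from."""

    parameters: dict
    provenance: str = "user"

    def __post_init__(self):
        missing = set(CALL_PARAMETERS) - set(self.parameters)
        if missing:
            raise ValueError(f"call model missing parameter sets: {sorted(missing)}")
        for key in CALL_PARAMETERS:
            coeffs = self.parameters[key]
            if set(coeffs) != {"intercept", "membrane", "turns"}:
                raise ValueError(f"bad coefficient keys for {key!r}: {set(coeffs)}")

    def predict(self, membrane_length: float, turns: float):
        """(min, peak, max) call frequencies in kHz for the given morphology."""
        if membrane_length <= 0 or turns <= 0:
            raise DomainError("membrane_length and turns must be positive, got "
                              f"{membrane_length}, {turns}")
        lm, lt = np.log10(membrane_length), np.log10(turns)
        out = []
        for key in CALL_PARAMETERS:
            c = self.parameters[key]
            out.append(float(10.0 ** (c["intercept"] + c["membrane"] * lm
                                      + c["turns"] * lt)))
        fmin, fpeak, fmax = out
        if fmin > fmax:
            warnings.warn(
                f"predicted minimum frequency ({fmin:.1f} kHz) exceeds maximum "
                f"({fmax:.1f} kHz); coefficients extrapolated beyond calibration",
                stacklevel=2)
        return fmin, fpeak, fmax


def load_builtin_model(name: str) -> CallFreqModel:
    """Load a built-in call-frequency coefficient set by name."""
    try:
        payload = json.loads(
            resources.files("cochlevo.data").joinpath(f"{name}.json").read_text())
    except FileNotFoundError as exc:
        raise KeyError(f"no built-in call model named {name!r}") from exc
    return CallFreqModel(parameters=payload["parameters"], provenance=payload["name"])


def predict_call_frequencies(membrane_length: float, turns: float,
                             model: CallFreqModel | str = "davies2013_phylo"):
    """(min, peak, max) echolocation call frequencies (kHz) for a cochlea of
    the given absolute membrane length (mm) and turn count."""
    if isinstance(model, str):
        model = load_builtin_model(model)
    return model.predict(membrane_length, turns)


# ---------------------------------------------------------------------------
# audiogram calibration
# ---------------------------------------------------------------------------

@dataclass
class HearingCalibration:
    """Four fitted hearing-limit regressions.

    ``fits`` maps 'hf30'/'hf60' (response: log10 high-frequency limit, kHz;
    predictor: log10 relative membrane length, mm/g^exponent) and
    'lf30'/'lf60' (response: log10 low-frequency limit; predictor:
    log10(membrane length) * turns) to :class:`~cochlevo.allometry.RegressionFit`
    objects.  ``mass_exponent`` records the relative-length scaling used.
    """

    fits: dict
    mass_exponent: float = 1.0 / 3.0
    n_species: int = 0

    def __post_init__(self):
        missing = set(LIMIT_KEYS) - set(self.fits)
        if missing:
            raise ValueError(f"calibration missing regressions: {sorted(missing)}")

    def predict(self, membrane_length: float, turns: float, mass: float) -> dict:
        if membrane_length <= 0 or turns <= 0 or mass <= 0:
            raise DomainError("morphology inputs must be positive")
        rel = relative_membrane_length(membrane_length, mass, self.mass_exponent)
        x_hi = np.log10(rel)
        x_lo = np.log10(membrane_length) * turns
        out = {}
        for key in LIMIT_KEYS:
            x = x_hi if key.startswith("hf") else x_lo
            out[key] = float(10.0 ** self.fits[key].predict([[x]])[0])
        return out

    def prediction_intervals(self, membrane_length: float, turns: float,
                             mass: float, level: float = 0.95) -> dict:
        """(lower, upper) kHz prediction intervals for each limit."""
        rel = relative_membrane_length(membrane_length, mass, self.mass_exponent)
        x_hi = np.log10(rel)
        x_lo = np.log10(membrane_length) * turns
        out = {}
        for key in LIMIT_KEYS:
            x = x_hi if key.startswith("hf") else x_lo
            lo, hi = self.fits[key].prediction_interval([[x]], level=level)
            out[key] = (float(10.0 ** lo[0]), float(10.0 ** hi[0]))
        return out

    def summary(self) -> str:
        lines = [f"Hearing calibration (n = {self.n_species} species, "
                 f"mass exponent {self.mass_exponent:.3f})"]
        for key in LIMIT_KEYS:
            fit = self.fits[key]
            pred = ("log10 rel. membrane" if key.startswith("hf")
                    else "log10(membrane) x turns")
            lines.append(f"  {key}: log10 kHz = {fit.params[0]:.3f} + "
                         f"{fit.params[1]:.3f} * {pred}  (R^2 = {fit.rsquared:.3f})")
        return "\n".join(lines)


def fit_hearing_calibration(audiograms: pd.DataFrame, traits: pd.DataFrame,
                            mass_exponent: float = 1.0 / 3.0) -> HearingCalibration:
    """Fit the four hearing-limit regressions from an audiogram table.

    ``audiograms`` needs columns species, hf30, hf60, lf30, lf60 (kHz);
    ``traits`` needs species, membrane_length, turns, mass.  The tables are
    joined on species; at least 4 joint species are required.
    """
    merged = audiograms[["species", *LIMIT_KEYS]].merge(
        traits[["species", "membrane_length", "turns", "mass"]], on="species")
    merged = merged.dropna(subset=["membrane_length", "turns", "mass", *LIMIT_KEYS])
    if len(merged) < 4:
        raise ValueError(
            f"need >= 4 species with both traits and audiogram limits, "
            f"got {len(merged)}")
    rel = merged["membrane_length"] / merged["mass"] ** mass_exponent
    x_hi = np.log10(rel.to_numpy(float))
    x_lo = np.log10(merged["membrane_length"].to_numpy(float)) * \
        merged["turns"].to_numpy(float)
    fits = {}
    for key in LIMIT_KEYS:
        x = x_hi if key.startswith("hf") else x_lo
        y = np.log10(merged[key].to_numpy(float))
        fits[key] = allometry.fit_ols(y, x)
    return HearingCalibration(fits=fits, mass_exponent=mass_exponent,
                              n_species=len(merged))


def predict_hearing_limits(membrane_length: float, turns: float, mass: float,
                           calibration: HearingCalibration) -> dict:
    """Hearing limits (kHz) at 30/60 dB for the given morphology; keys
    hf30, hf60 (high-frequency limits) and lf30, lf60 (low-frequency)."""
    return calibration.predict(membrane_length, turns, mass)
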