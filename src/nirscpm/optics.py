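"""Raw optical data to hemoglobin concentration changes.

Continuous-wave NIRS measures attenuation changes of near-infrared light at
two wavelengths (here 695 and 830 nm). Under the modified Beer-Lambert law a
change in optical density at wavelength lambda is a linear mixture of the
oxy- and deoxy-hemoglobin concentration changes,

    dOD(lambda) = [eps_HbO(lambda) * dHbO + eps_HbR(lambda) * dHbR] * d * DPF,

where d is the source-detector separation, DPF the differential pathlength
factor correcting d for photon scattering, and eps the molar extinction
coefficients. With two wavelengths this is a 2x2 linear system per channel
and time point, solved exactly.

This module also provides steady-state trimming and an automated
spike/shift artifact-flagging heuristic (a deterministic stand-in for
manual visual inspection of motion artifacts).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

#: Molar extinction coefficients, cm^-1 M^-1, from the standard tabulated
#: compilation for human hemoglobin.  Keyed by wavelength (nm); values are
#: (eps_HbO, eps_HbR).  Overridable via :func:`load_extinction_table`.
DEFAULT_EXTINCTION: dict[int, tuple[float, float]] = {
    695: (290.0, 1922.8),
    830: (974.0, 693.04),
}

WAVELENGTHS = (695, 830)


def load_extinction_table(path) -> dict[int, tuple[float, float]]:
    """Read an extinction table from a delimited text file.

    Expected columns: ``wavelength_nm``, ``eps_hbo``, ``eps_hbr`` (cm^-1 M^-1).
    """
    tab = pd.read_csv(path, sep=None, engine="python")
    required = {"wavelength_nm", "eps_hbo", "eps_hbr"}
    if not required.issubset(tab.columns):
        raise InputError(f"extinction table must have columns {sorted(required)}")
    return {
        int(row.wavelength_nm): (float(row.eps_hbo), float(row.eps_hbr))
        for row in tab.itertuples()
    }


@dataclass
class BeerLambertParams:
    """Parameters of the modified Beer-Lambert conversion.

    extinction maps wavelength (nm) -> (eps_HbO, eps_HbR) in cm^-1 M^-1;
    dpf is the (single, wavelength-shared) differential pathlength factor;
    distance_mm the source-detector separation. The effective optical
    pathlength is distance * dpf.
    """

    extinction: dict[int, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EXTINCTION)
    )
    dpf: float = 6.26
    distance_mm: float = 30.0
    max_condition: float = 1e6
    unit: str = "uM"  # reporting unit for concentration changes: "uM" or "M"

    def extinction_matrix(self) -> np.ndarray:
        """2x2 matrix E with rows per wavelength, columns (HbO, HbR)."""
        try:
            rows = [self.extinction[w] for w in WAVELENGTHS]
        except KeyError as exc:
            raise ConfigurationError(f"extinction table missing wavelength {exc}")
        return np.asarray(rows, dtype=float)

    def effective_pathlength_mm(self) -> float:
        return self.distance_mm * self.dpf

    def validate(self) -> None:
        E = self.extinction_matrix()
        if not np.all(np.isfinite(E)) or np.any(E < 0):
            raise ConfigurationError("extinction coefficients must be finite and >= 0")
        cond = np.linalg.cond(E)
        if not np.isfinite(cond) or cond > self.max_condition:
            raise ConfigurationError(
                f"extinction matrix ill-conditioned (cond={cond:.3g} > {self.max_condition:.3g})"
            )
        if self.dpf <= 0 or self.distance_mm <= 0:
            raise ConfigurationError("dpf and distance_mm must be positive")
        if self.unit not in ("uM", "M"):
            raise ConfigurationError(f"unknown concentration unit {self.unit!r}")


def _check_matrix(name: str, a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2:
        raise InputError(f"{name} must be a channels x time matrix, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise InputError(f"{name} contains non-finite values")
    return a


@dataclass
class IntensityRecording:
    """Two-wavelength optical-density changes for one participant (channels x time)."""

    participant_id: str
    od_695: np.ndarray
    od_830: np.ndarray
    sampling_rate: float
    distance_mm: float = 30.0

    def validate(self) -> None:
        a = _check_matrix("od_695", self.od_695)
        b = _check_matrix("od_830", self.od_830)
        if a.shape != b.shape:
            raise InputError(
                f"wavelength matrices differ in shape: {a.shape} vs {b.shape}"
            )
        if self.sampling_rate <= 0:
            raise InputError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.od_695.shape[0]

    @property
    def n_samples(self) -> int:
        return self.od_695.shape[1]


@dataclass
class HemoSeries:
    """Channel x time HbO/HbR concentration changes plus an artifact mask.

    Concentrations are in the unit recorded in ``unit`` (micromolar by
    default).  ``artifact_mask`` is True where a sample is flagged.
    """

    participant_id: str
    hbo: np.ndarray
    hbr: np.ndarray
    sampling_rate: float
    artifact_mask: np.ndarray | None = None
    unit: str = "uM"

    def __post_init__(self):
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(np.shape(self.hbo), dtype=bool)

    def validate(self) -> None:
        a = _check_matrix("hbo", self.hbo)
        b = _check_matrix("hbr", self.hbr)
        if a.shape != b.shape:
            raise InputError(f"hbo/hbr shape mismatch: {a.shape} vs {b.shape}")
        m = np.asarray(self.artifact_mask)
        if m.shape != a.shape or m.dtype != bool:
            raise InputError("artifact_mask must be a boolean matrix matching hbo")
        if self.sampling_rate <= 0:
            raise InputError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[1]

    def chromophore(self, which: str) -> np.ndarray:
        key = which.lower()
        if key == "hbo":
            return self.hbo
        if key == "hbr":
            return self.hbr
        raise InputError(f"unknown chromophore {which!r} (expected 'HbO' or 'HbR')")


def forward_od(
    hbo: np.ndarray, hbr: np.ndarray, params: BeerLambertParams
) -> tuple[np.ndarray, np.ndarray]:
    """Forward Beer-Lambert model: concentration changes -> dOD at 695/830 nm.

    Inputs are in ``params.unit``; output optical densities are unitless.
    Used by the synthetic-data generator and by round-trip tests.
    """
    params.validate()
    scale = 1e-6 if params.unit == "uM" else 1.0  # to molar
    L_cm = params.effective_pathlength_mm() / 10.0
    E = params.extinction_matrix()
    hbo = np.asarray(hbo, float) * scale
    hbr = np.asarray(hbr, float) * scale
    od695 = (E[0, 0] * hbo + E[0, 1] * hbr) * L_cm
    od830 = (E[1, 0] * hbo + E[1, 1] * hbr) * L_cm
    return od695, od830


def od_to_hemoglobin(rec: IntensityRecording, params: BeerLambertParams | None = None) -> HemoSeries:
    """Invert the modified Beer-Lambert 2x2 system for every channel/sample."""
    params = params if params is not None else BeerLambertParams(distance_mm=rec.distance_mm)
    rec.validate()
    params.validate()
    L_cm = params.effective_pathlength_mm() / 10.0
    A = np.linalg.inv(params.extinction_matrix()) / L_cm
    hbo = A[0, 0] * rec.od_695 + A[0, 1] * rec.od_830  # molar
    hbr = A[1, 0] * rec.od_695 + A[1, 1] * rec.od_830
    if params.unit == "uM":
        hbo = hbo * 1e6
        hbr = hbr * 1e6
    return HemoSeries(
        participant_id=rec.participant_id,
        hbo=hbo,
        hbr=hbr,
        sampling_rate=rec.sampling_rate,
        unit=params.unit,
    )


def trim_steady_state(series: HemoSeries, trim_seconds: float = 10.0) -> HemoSeries:
    """Drop round(trim_seconds * fs) samples from each end of the recording."""
    series.validate()
    if trim_seconds < 0:
        raise InputError("trim_seconds must be >= 0")
    n = int(round(trim_seconds * series.sampling_rate))
    if n == 0:
        return replace(series)
    if series.n_samples <= 2 * n:
        raise InputError(
            f"series of {series.n_samples} samples too short to trim {n} from each end"
        )
    sl = slice(n, series.n_samples - n)
    return replace(
        series,
        hbo=series.hbo[:, sl].copy(),
        hbr=series.hbr[:, sl].copy(),
        artifact_mask=series.artifact_mask[:, sl].copy(),
    )


def _robust_z(diff: np.ndarray) -> np.ndarray:
    med = np.median(diff, axis=1, keepdims=True)
    mad = np.median(np.abs(diff - med), axis=1, keepdims=True)
    scale = 1.4826 * mad
    z = np.zeros_like(diff)
    ok = scale[:, 0] > 0
    z[ok] = (diff[ok] - med[ok]) / scale[ok]
    return z


def flag_artifacts(
    series: HemoSeries, spike_z: float = 7.0, shift_window: int = 5
) -> HemoSeries:
    """Flag motion-like artifacts from the robust z-score of first differences.

    A sample is flagged when the robust z-score (median/MAD) of the first
    difference of either chromophore exceeds ``spike_z``; flags are dilated
    by ``shift_window`` samples on each side to cover baseline shifts.
    Constant channels have zero differences and are never flagged.
    """
    series.validate()
    if spike_z <= 0 or shift_window < 0:
        raise InputError("spike_z must be > 0 and shift_window >= 0")
    mask = np.zeros_like(series.artifact_mask)
    for data in (series.hbo, series.hbr):
        d = np.diff(data, axis=1)
        z = np.abs(_robust_z(d))
        hit = z > spike_z
        # a difference spike implicates both samples around it
        mask[:, :-1] |= hit
        mask[:, 1:] |= hit
    if shift_window > 0:
        kernel = np.ones(2 * shift_window + 1, dtype=bool)
        mask = np.apply_along_axis(
            lambda row: np.convolve(row, kernel, mode="same") > 0, 1, mask
        )
    return replace(series, artifact_mask=mask | series.artifact_mask)


def flagged_fraction(series: HemoSeries) -> np.ndarray:
    """Per-channel fraction of flagged samples (QC quantity)."""
    return np.asarray(series.artifact_mask, bool).mean(axis=1)


def interpolate_flagged(series: HemoSeries) -> HemoSeries:
    """Linearly interpolate over flagged samples and clear the mask."""
    series.validate()
    t = np.arange(series.n_samples)
    hbo = series.hbo.copy()
    hbr = series.hbr.copy()
    for c in range(series.n_channels):
        bad = series.artifact_mask[c]
        if bad.any() and not bad.all():
            for arr in (hbo, hbr):
                arr[c, bad] = np.interp(t[bad], t[~bad], arr[c, ~bad])
    return replace(
        series, hbo=hbo, hbr=hbr, artifact_mask=np.zeros_like(series.artifact_mask)
    )
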