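"""Modified Beer-Lambert law constants shared by the simulator and the
preprocessing inverse, so forward/inverse round trips are exact.

Extinction coefficients are the standard tabulated values for oxy- and
deoxy-hemoglobin at 690 and 830 nm, in cm^-1 per mM.  The differential
pathlength factor (DPF) and the source-detector separation convert the
geometric distance to an effective photon path; both are configurable and
recorded in every output's provenance.
"""

from __future__ import annotations

import numpy as np

WAVELENGTHS = (690.0, 830.0)  # nm

# rows: wavelength (690, 830); columns: chromophore (HbO2, HbR); cm^-1 mM^-1
EXTINCTION = np.array(
    [
        [0.276, 2.052],
        [0.974, 0.693],
    ]
)

DEFAULT_DPF = (6.0, 6.0)          # dimensionless, per wavelength
DEFAULT_SEPARATION_CM = 3.0       # source-detector distance


def mbll_matrix(
    dpf: tuple[float, float] = DEFAULT_DPF,
    separation_cm: float = DEFAULT_SEPARATION_CM,
    extinction: np.ndarray | None = None,
) -> np.ndarray:
    """2x2 matrix A with od[wavelength] = A @ [HbO, HbR] (concentrations in mM)."""
    E = EXTINCTION if extinction is None else np.asarray(extinction, dtype=float)
    if E.shape != (2, 2):
        raise ValueError("extinction matrix must be 2x2 (wavelength x chromophore)")
    path = separation_cm * np.asarray(dpf, dtype=float)  # effective path per wavelength
    A = E * path[:, None]
    if abs(np.linalg.det(A)) < 1e-12:
        raise ValueError("singular extinction/pathlength matrix; cannot invert MBLL")
    return A


def concentration_to_od(oxy_uM: np.ndarray, deoxy_uM: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Forward MBLL: (channels x time) HbO/HbR in µM -> OD (2 x channels x time)."""
    conc_mM = np.stack([oxy_uM, deoxy_uM]) * 1e-3  # (2, channels, time)
    return np.einsum("wc,cnt->wnt", A, conc_mM)


def od_to_concentration_pair(od: np.ndarray, A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse MBLL: OD (2 x channels x time) -> (oxy, deoxy) in µM."""
    conc_mM = np.einsum("cw,wnt->cnt", np.linalg.inv(A), od)
    oxy, deoxy = conc_mM * 1e3
    return oxy, deoxy
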