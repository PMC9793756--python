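"""Data containers for spectral calibration.

A :class:`SpectrumSet` is the X block: an absorbance matrix with a
wavelength axis in nm and per-sample identifiers.  A :class:`TargetVector`
is one y block: the concentration of a single mixture component in % g/g.
Both validate their invariants on construction so that downstream code can
assume clean inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpectrumSet",
    "TargetVector",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_targets_csv",
    "write_targets_csv",
]


@dataclass
class SpectrumSet:
    """Absorbance spectra of a set of samples on a common wavelength grid.

    Parameters
    ----------
    wavelengths : array of float
        Wavelength axis in nm, strictly increasing, no duplicates.
    absorbance : array of float, shape (n_samples, n_wavelengths)
        Unitless absorbance values; must be finite.
    sample_ids : list of str, optional
        One identifier per sample; autogenerated ``s000, s001, ...`` when
        omitted.
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float).ravel()
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if self.absorbance.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"absorbance has {self.absorbance.shape[1]} columns but "
                f"{self.wavelengths.size} wavelengths were given"
            )
        if self.wavelengths.size and np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")
        if not self.sample_ids:
            self.sample_ids = [f"s{i:03d}" for i in range(self.absorbance.shape[0])]
        elif len(self.sample_ids) != self.absorbance.shape[0]:
            raise ValueError("sample_ids length does not match number of samples")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths.size

    def take_samples(self, idx) -> "SpectrumSet":
        """Row-subset by sample index array, preserving identifiers."""
        idx = np.asarray(idx, dtype=int)
        return SpectrumSet(
            wavelengths=self.wavelengths,
            absorbance=self.absorbance[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
        )


@dataclass
class TargetVector:
    """Concentration of one component (% g/g) for each sample."""

    values: np.ndarray
    component_name: str = "component"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("target values contain non-finite entries")
        if np.any((self.values < 0) | (self.values > 100)):
            raise ValueError("concentrations must lie in [0, 100] % g/g")

    def __len__(self) -> int:
        return self.values.size

    def take(self, idx) -> "TargetVector":
        idx = np.asarray(idx, dtype=int)
        return TargetVector(self.values[idx], self.component_name)


# ---------------------------------------------------------------------------
# CSV round-trip.  Spectra files: header "sample_id,<nm_1>,...,<nm_j>",
# one row per sample.  Target files: "sample_id" plus one column per
# component.  UTF-8, "." decimal, comma delimiter throughout.
# ---------------------------------------------------------------------------

def read_spectra_csv(path) -> SpectrumSet:
    df = pd.read_csv(path)
    if df.columns[0] != "sample_id":
        raise ValueError("first column of a spectra CSV must be 'sample_id'")
    wavelengths = np.array([float(c) for c in df.columns[1:]])
    return SpectrumSet(
        wavelengths=wavelengths,
        absorbance=df.iloc[:, 1:].to_numpy(dtype=float),
        sample_ids=df["sample_id"].astype(str).tolist(),
    )


def write_spectra_csv(spectra: SpectrumSet, path) -> None:
    df = pd.DataFrame(
        spectra.absorbance,
        columns=[format(w, "g") for w in spectra.wavelengths],
    )
    df.insert(0, "sample_id", spectra.sample_ids)
    df.to_csv(path, index=False)


def read_targets_csv(path, component: str | None = None):
    """Read target concentrations.

    Returns a single :class:`TargetVector` when ``component`` is given,
    otherwise a dict mapping every component column to its vector.
    """
    df = pd.read_csv(path)
    if df.columns[0] != "sample_id":
        raise ValueError("first column of a targets CSV must be 'sample_id'")
    if component is not None:
        if component not in df.columns:
            raise KeyError(f"component {component!r} not in {list(df.columns[1:])}")
        return TargetVector(df[component].to_numpy(dtype=float), component)
    return {
        c: TargetVector(df[c].to_numpy(dtype=float), c) for c in df.columns[1:]
    }


def write_targets_csv(targets: dict[str, TargetVector], sample_ids, path) -> None:
    df = pd.DataFrame({"sample_id": list(sample_ids)})
    for name, tv in targets.items():
        df[name] = tv.values
    df.to_csv(path, index=False)
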