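"""Readers, writers and configuration for the monitoring pipeline.

Spectra and basis spectra travel as UTF-8 tab-delimited text with ``# key:
value`` metadata headers; fiber geometry as YAML with explicit units in the
key names; volumes in NIfTI convention through nibabel; run parameters as a
YAML-serializable :class:`RunConfig`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import map_coordinates

from .geometry import DEFAULT_ZONE_RADIUS_MM, CDFSection
from .mri import ImageVolume, LabelVolume
from .optics import DEFAULT_MU_S_PRIME, LOOKUP_GRID
from .spectra import DETECTION_MULTIPLIER, FluorescenceBasis, Spectrum
from .stats import DISTANCE_CUTOFF_MM

__all__ = [
    "RunConfig",
    "CaseInputs",
    "apply_affine",
    "resample_image",
    "read_spectrum",
    "write_spectrum",
    "read_basis",
    "write_basis",
    "read_geometry",
    "write_geometry",
    "load_label",
    "save_label",
    "load_image",
    "save_image",
    "write_case",
    "load_case_inputs",
]


@dataclass
class RunConfig:
    """All tunable pipeline parameters; defaults are the analysis' standards."""

    mu_s_prime: float = DEFAULT_MU_S_PRIME
    lookup_min: float = LOOKUP_GRID[0]
    lookup_max: float = LOOKUP_GRID[1]
    lookup_step: float = LOOKUP_GRID[2]
    zone_radius_mm: float = DEFAULT_ZONE_RADIUS_MM
    zone_grid_mm: float = 0.1
    distance_cutoff_mm: float = DISTANCE_CUTOFF_MM
    detection_multiplier: float = DETECTION_MULTIPLIER
    p0: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "mu_s_prime", "lookup_min", "lookup_max", "lookup_step",
            "zone_radius_mm", "zone_grid_mm", "distance_cutoff_mm",
            "detection_multiplier", "p0",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class CaseInputs:
    """Everything the pipeline needs for one case."""

    case_id: str
    sections: list
    spectra: list
    basis: FluorescenceBasis
    tumor: LabelVolume | None = None
    hyper: LabelVolume | None = None
    wm_spheres: list = field(default_factory=list)
    t1: ImageVolume | None = None


# ---------------------------------------------------------------------------
# affine plumbing
# ---------------------------------------------------------------------------


def apply_affine(points: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Apply a 4x4 affine to an (n, 3) array of points."""
    affine = np.asarray(affine, dtype=float)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-15:
        raise ValueError("affine is singular")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return pts @ affine[:3, :3].T + affine[:3, 3]


def resample_image(
    image: ImageVolume, shape: tuple, affine: np.ndarray, order: int = 1
) -> ImageVolume:
    """Resample a scalar image onto a target grid (linear by default)."""
    affine = np.asarray(affine, dtype=float)
    idx = np.indices(shape).reshape(3, -1)
    world = affine[:3, :3] @ idx + affine[:3, 3:4]
    src = np.linalg.inv(image.affine[:3, :3]) @ (world - image.affine[:3, 3:4])
    vals = map_coordinates(image.data, src, order=order, mode="nearest")
    return ImageVolume(vals.reshape(shape), affine)


# ---------------------------------------------------------------------------
# delimited-text spectra
# ---------------------------------------------------------------------------


def write_spectrum(path, spectrum: Spectrum) -> None:
    lines = [f"# {k}: {v}" for k, v in sorted(spectrum.meta.items())]
    lines.append("wavelength_nm\tcounts_per_ms")
    lines += [
        f"{wl:.6g}\t{it:.10g}"
        for wl, it in zip(spectrum.wavelengths, spectrum.intensities)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_spectrum(path) -> Spectrum:
    meta = {}
    rows = []
    header_seen = False
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
        elif not header_seen:
            header_seen = True
        else:
            a, b = line.split("\t")
            rows.append((float(a), float(b)))
    if not rows:
        raise ValueError(f"no data rows in spectrum file {path}")
    arr = np.asarray(rows)
    return Spectrum(arr[:, 0], arr[:, 1], meta=meta)


def write_basis(path, basis: FluorescenceBasis) -> None:
    df = pd.DataFrame(
        {"wavelength_nm": basis.wavelengths, "ppix": basis.ppix, "auto": basis.auto}
    )
    df.to_csv(path, sep="\t", index=False)


def read_basis(path) -> FluorescenceBasis:
    df = pd.read_csv(path, sep="\t")
    return FluorescenceBasis(
        df["wavelength_nm"].to_numpy(), df["ppix"].to_numpy(), df["auto"].to_numpy()
    )


# ---------------------------------------------------------------------------
# geometry config
# ---------------------------------------------------------------------------


def write_geometry(path, sections: list[CDFSection]) -> None:
    payload = {
        "fibers": [
            {
                "id": s.fiber_id,
                "proximal_xyz_mm": [float(v) for v in s.proximal],
                "distal_xyz_mm": [float(v) for v in s.distal],
                "diffuser_length_mm": float(s.length_mm),
                "power_mW_per_cm": float(s.power_mw_per_cm),
            }
            for s in sections
        ]
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_geometry(path) -> list[CDFSection]:
    payload = yaml.safe_load(Path(path).read_text())
    return [
        CDFSection(
            str(f["id"]),
            np.asarray(f["proximal_xyz_mm"], dtype=float),
            np.asarray(f["distal_xyz_mm"], dtype=float),
            float(f["diffuser_length_mm"]),
            float(f.get("power_mW_per_cm", 200.0)),
        )
        for f in payload["fibers"]
    ]


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------


def save_label(path, label: LabelVolume) -> None:
    nib.save(nib.Nifti1Image(label.mask.astype(np.uint8), label.affine), str(path))


def load_label(path, role: str = "label") -> LabelVolume:
    img = nib.load(str(path))
    return LabelVolume(np.asarray(img.dataobj) > 0, img.affine, role=role)


def save_image(path, image: ImageVolume) -> None:
    nib.save(nib.Nifti1Image(image.data.astype(np.float32), image.affine), str(path))


def load_image(path) -> ImageVolume:
    img = nib.load(str(path))
    return ImageVolume(np.asarray(img.dataobj, dtype=float), img.affine)


# ---------------------------------------------------------------------------
# whole-case round trip (synthetic cases -> on-disk layout -> pipeline inputs)
# ---------------------------------------------------------------------------


def write_case(case, directory) -> Path:
    """Write a synthetic case to the pipeline's on-disk layout."""
    directory = Path(directory)
    (directory / "spectra").mkdir(parents=True, exist_ok=True)
    write_geometry(directory / "geometry.yaml", case.sections)
    write_basis(directory / "basis.tsv", case.basis)
    for k, spectrum in enumerate(case.spectra):
        meta = spectrum.meta
        name = f"{meta.get('emitter', 'E')}_{meta.get('detector', 'D')}_{meta.get('phase', k)}.tsv"
        write_spectrum(directory / "spectra" / name, spectrum)
    save_label(directory / "tumor.nii", case.tumor)
    save_label(directory / "hyperintensity.nii", case.hyper)
    for k, sphere in enumerate(case.wm_spheres):
        save_label(directory / f"wm_sphere_{k}.nii", sphere)
    save_image(directory / "t1.nii", case.t1)
    truth = {
        "seed": int(case.truth.seed),
        "p0": float(case.truth.p0),
        "noise_fraction": float(case.truth.noise_fraction),
        "noise_floor": float(case.truth.noise_floor),
        "background_mu_a": float(case.truth.background_mu_a),
        "mu_s_prime": float(case.truth.mu_s_prime),
        "i_t1": float(case.truth.i_t1),
        "blobs": [
            {
                "center_mm": [float(v) for v in b.center],
                "radius_mm": float(b.radius_mm),
                "delta_mu_a": float(b.delta_mu_a),
            }
            for b in case.truth.blobs
        ],
        "pairs": {
            pid: {
                k: (bool(v) if isinstance(v, (bool, np.bool_)) else float(v))
                for k, v in dataclasses.asdict(pt).items()
            }
            for pid, pt in case.truth.pairs.items()
        },
    }
    (directory / "truth.yaml").write_text(yaml.safe_dump(truth, sort_keys=False))
    return directory


def load_case_inputs(directory, case_id: str | None = None) -> CaseInputs:
    """Load a case directory written by :func:`write_case` (or hand-assembled)."""
    directory = Path(directory)
    if not (directory / "geometry.yaml").exists():
        raise FileNotFoundError(
            f"stage 'geometry': missing input file {directory / 'geometry.yaml'}"
        )
    sections = read_geometry(directory / "geometry.yaml")
    basis = read_basis(directory / "basis.tsv")
    spectra = [read_spectrum(p) for p in sorted((directory / "spectra").glob("*.tsv"))]
    if not spectra:
        raise FileNotFoundError(f"stage 'spectra': no spectra found under {directory / 'spectra'}")

    def maybe_label(name, role):
        p = directory / name
        return load_label(p, role) if p.exists() else None

    wm = [
        load_label(p, "wm_sphere") for p in sorted(directory.glob("wm_sphere_*.nii"))
    ]
    t1_path = directory / "t1.nii"
    return CaseInputs(
        case_id=case_id or directory.name,
        sections=sections,
        spectra=spectra,
        basis=basis,
        tumor=maybe_label("tumor.nii", "tumor"),
        hyper=maybe_label("hyperintensity.nii", "hyperintensity"),
        wm_spheres=wm,
        t1=load_image(t1_path) if t1_path.exists() else None,
    )
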