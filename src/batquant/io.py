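"""File formats: NIfTI volumes with YAML sidecars, spectrum CSVs, tables.

Volumes travel as NIfTI-1 (.nii/.nii.gz) with the acquisition metadata
(dose, weight, isotope, unit, frame schedule) in a YAML sidecar.  Spectra
are CSV with a commented YAML header (``# key: value`` lines) holding the
field strength, timestamp and tissue label; a series manifest is a YAML
list of files in time order.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .biodist import OrganCount
from .emission import EmissionImage, VOIBox
from .mrs import Spectrum

__all__ = [
    "save_image", "load_image",
    "save_spectrum", "load_spectrum", "load_series_manifest",
    "load_voi_box", "load_organ_counts",
]


def save_image(image: EmissionImage, path: str | Path,
               sidecar: str | Path | None = None) -> None:
    path = Path(path)
    affine = np.diag(list(image.spacing_mm) + [1.0])
    nib.save(nib.Nifti1Image(image.voxels.astype(np.float64), affine), path)
    meta = {
        "value_unit": image.value_unit,
        "modality": image.modality,
        "injected_dose_Bq": float(image.injected_dose_Bq),
        "body_weight_g": float(image.body_weight_g),
        "isotope": image.isotope,
        "injection_time_s": float(image.injection_time_s),
        "frame_schedule": [[float(a), float(b)]
                           for a, b in image.frame_schedule],
    }
    if sidecar is None:
        sidecar = path.with_suffix("").with_suffix(".yaml") \
            if path.name.endswith(".nii.gz") else path.with_suffix(".yaml")
    Path(sidecar).write_text(yaml.safe_dump(meta))


def load_image(path: str | Path, sidecar: str | Path | None = None) -> EmissionImage:
    path = Path(path)
    if sidecar is None:
        sidecar = path.with_suffix("").with_suffix(".yaml") \
            if path.name.endswith(".nii.gz") else path.with_suffix(".yaml")
    meta = yaml.safe_load(Path(sidecar).read_text())
    img = nib.load(path)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return EmissionImage(
        voxels=np.asarray(img.dataobj, dtype=float),
        spacing_mm=spacing,
        value_unit=meta["value_unit"],
        modality=meta["modality"],
        injected_dose_Bq=meta["injected_dose_Bq"],
        body_weight_g=meta["body_weight_g"],
        isotope=meta["isotope"],
        injection_time_s=meta.get("injection_time_s", 0.0),
        frame_schedule=tuple((a, b) for a, b in meta.get("frame_schedule", [])),
    )


def save_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    header = {
        "field_strength_T": float(spectrum.field_strength_T),
        "timestamp_s": float(spectrum.timestamp_s),
        "tissue_label": spectrum.tissue_label,
    }
    lines = [f"# {k}: {v}" for k, v in header.items()]
    amp = spectrum.amplitude
    if np.iscomplexobj(amp):
        lines.append("ppm,real,imag")
        for p, a in zip(spectrum.ppm, amp):
            lines.append(f"{p:.9g},{a.real:.9g},{a.imag:.9g}")
    else:
        lines.append("ppm,magnitude")
        for p, a in zip(spectrum.ppm, amp):
            lines.append(f"{p:.9g},{a:.9g}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_spectrum(path: str | Path) -> Spectrum:
    text = Path(path).read_text().splitlines()
    header: dict = {}
    body_start = 0
    for i, line in enumerate(text):
        if line.startswith("#"):
            header.update(yaml.safe_load(line[1:].strip() + "\n") or {})
        else:
            body_start = i
            break
    from io import StringIO
    df = pd.read_csv(StringIO("\n".join(text[body_start:])))
    if {"real", "imag"} <= set(df.columns):
        amp = df["real"].to_numpy() + 1j * df["imag"].to_numpy()
    else:
        amp = df[df.columns[1]].to_numpy(dtype=float)
    return Spectrum(
        ppm=df["ppm"].to_numpy(dtype=float),
        amplitude=amp,
        field_strength_T=float(header.get("field_strength_T", 7.0)),
        timestamp_s=float(header.get("timestamp_s", 0.0)),
        tissue_label=str(header.get("tissue_label", "BAT")),
    )


def load_series_manifest(path: str | Path) -> list[Spectrum]:
    """Load a YAML manifest: {files: [spectrum1.csv, ...]} in time order."""
    path = Path(path)
    manifest = yaml.safe_load(path.read_text())
    files = manifest["files"] if isinstance(manifest, dict) else manifest
    return [load_spectrum(path.parent / f) for f in files]


def load_voi_box(path: str | Path) -> VOIBox:
    """YAML VOI box: {bounds: [[x0, x1], [y0, y1], [z0, z1]]}."""
    data = yaml.safe_load(Path(path).read_text())
    bounds = data["bounds"] if isinstance(data, dict) else data
    return VOIBox(bounds=tuple(tuple(b) for b in bounds))


def load_organ_counts(path: str | Path, isotope: str) -> list[OrganCount]:
    """Dissection CSV with columns organ, weight_g, activity_Bq, count_time_s."""
    df = pd.read_csv(path)
    return [
        OrganCount(organ=str(r.organ), weight_g=float(r.weight_g),
                   activity_Bq=float(r.activity_Bq),
                   count_time_s=float(r.count_time_s), isotope=isotope)
        for r in df.itertuples()
    ]
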