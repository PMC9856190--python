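"""Reading and writing spectra.

Two plain-text interchange formats:

* JSON-lines — one record per spectrum (metadata plus intensity array);
  round-trips the full cohort including the series grouping.
* wide CSV — first column wavenumber, one column per spectrum with a
  ``patient|sample|class|component|point|polarization`` header; handy
  for spreadsheets and external tools.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import ANGLES_DEG, Cohort, PolarizationSeries, Spectrum, WavenumberGrid

__all__ = [
    "write_jsonl",
    "read_jsonl",
    "write_wide_csv",
    "read_wide_csv",
]


def _spectrum_record(s: Spectrum) -> dict:
    return {
        "patient_id": s.patient_id,
        "sample_id": s.sample_id,
        "tissue_class": s.tissue_class,
        "component": s.component,
        "point_index": s.point_index,
        "polarization": "conventional" if s.is_conventional else s.polarization_deg,
        "grid": {
            "start": s.grid.start,
            "stop": s.grid.stop,
            "n_channels": s.grid.n_channels,
        },
        "intensities": [round(v, 6) for v in s.intensities.tolist()],
    }


def _record_spectrum(rec: dict) -> Spectrum:
    grid = WavenumberGrid(**rec["grid"])
    pol = rec.get("polarization", "conventional")
    return Spectrum(
        grid=grid,
        intensities=np.asarray(rec["intensities"], dtype=float),
        patient_id=rec.get("patient_id", ""),
        sample_id=rec.get("sample_id", ""),
        tissue_class=rec.get("tissue_class", ""),
        component=rec.get("component"),
        point_index=int(rec.get("point_index", 0)),
        polarization_deg=None if pol == "conventional" else float(pol),
    )


def write_jsonl(cohort: Cohort, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        if cohort.seed is not None:
            fh.write(json.dumps({"_meta": {"seed": cohort.seed}}) + "\n")
        for ser in cohort.series:
            for s in list(ser.spectra) + [ser.conventional]:
                fh.write(json.dumps(_spectrum_record(s)) + "\n")
    return path


def read_jsonl(path: str | Path) -> Cohort:
    spectra: list[Spectrum] = []
    seed = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            if "_meta" in rec:
                seed = rec["_meta"].get("seed")
                continue
            spectra.append(_record_spectrum(rec))
    if not spectra:
        raise ValueError(f"no spectra found in {path}")

    groups: dict[tuple, dict] = {}
    for s in spectra:
        key = (s.patient_id, s.sample_id, s.point_index)
        g = groups.setdefault(key, {"polarized": [], "conventional": None})
        if s.is_conventional:
            g["conventional"] = s
        else:
            g["polarized"].append(s)
    series = []
    for key, g in groups.items():
        if g["conventional"] is None or len(g["polarized"]) != 12:
            raise ValueError(
                f"point {key} is incomplete: needs 12 polarized spectra and one "
                f"conventional (got {len(g['polarized'])} polarized, "
                f"conventional={'yes' if g['conventional'] else 'no'})"
            )
        series.append(
            PolarizationSeries(
                spectra=sorted(g["polarized"], key=lambda s: s.polarization_deg),
                conventional=g["conventional"],
            )
        )
    return Cohort(series=series, grid=spectra[0].grid, seed=seed)


def write_wide_csv(cohort: Cohort, path: str | Path) -> Path:
    path = Path(path)
    cols = {"wavenumber": cohort.grid.wavenumbers}
    for ser in cohort.series:
        for s in list(ser.spectra) + [ser.conventional]:
            pol = "conventional" if s.is_conventional else f"{s.polarization_deg:g}"
            name = "|".join(
                [
                    s.patient_id,
                    s.sample_id,
                    s.tissue_class,
                    s.component or "",
                    str(s.point_index),
                    pol,
                ]
            )
            cols[name] = s.intensities
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6g")
    return path


def read_wide_csv(path: str | Path) -> Cohort:
    df = pd.read_csv(path)
    if "wavenumber" not in df.columns:
        raise ValueError("wide CSV must have a 'wavenumber' first column")
    w = df["wavenumber"].to_numpy()
    grid = WavenumberGrid(float(w[0]), float(w[-1]), len(w))
    spectra = []
    for name in df.columns:
        if name == "wavenumber":
            continue
        patient, sample, tclass, comp, point, pol = name.split("|")
        spectra.append(
            Spectrum(
                grid=grid,
                intensities=df[name].to_numpy(dtype=float),
                patient_id=patient,
                sample_id=sample,
                tissue_class=tclass,
                component=comp or None,
                point_index=int(point),
                polarization_deg=None if pol == "conventional" else float(pol),
            )
        )
    groups: dict[tuple, dict] = {}
    for s in spectra:
        key = (s.patient_id, s.sample_id, s.point_index)
        g = groups.setdefault(key, {"polarized": [], "conventional": None})
        if s.is_conventional:
            g["conventional"] = s
        else:
            g["polarized"].append(s)
    series = [
        PolarizationSeries(
            spectra=sorted(g["polarized"], key=lambda s: s.polarization_deg),
            conventional=g["conventional"],
        )
        for g in groups.values()
    ]
    return Cohort(series=series, grid=grid)
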