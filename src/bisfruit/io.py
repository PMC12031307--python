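"""CSV/JSON interchange for spectra, fits, truth tables and features.

Spectrum CSV layout: one row per sample x day with metadata columns
(sample_id, day, size, storage, diameter_mm) followed by |Z| columns
``zmod_001..zmod_NNN`` (Ohm) and phase columns ``phase_001..phase_NNN``
(degrees).  The frequency grid is written once to a JSON sidecar next to
the CSV.  Floats carry 12+ significant digits so round-trips preserve
the data to fitting precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .ec_fit import FitResult
from .ec_model import (
    EC_PARAMETER_NAMES,
    FrequencyGrid,
    ImpedanceSpectrum,
    SpectrumMetadata,
    from_polar,
)
from .features import FeatureTable
from .synthetic import SampleRecord

FLOAT_FORMAT = "%.12g"


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".grid.json")


def write_spectra_csv(spectra: Sequence[ImpedanceSpectrum], path) -> None:
    path = Path(path)
    grid = spectra[0].grid
    n = len(grid)
    rows = []
    for s in spectra:
        if len(s.grid) != n or not np.allclose(s.grid.frequencies, grid.frequencies):
            raise ValueError("all spectra must share one frequency grid")
        m = s.metadata
        row = {
            "sample_id": m.sample_id,
            "day": m.day,
            "size": m.size,
            "storage": m.storage,
            "diameter_mm": m.diameter_mm,
        }
        for i, v in enumerate(s.magnitude):
            row[f"zmod_{i + 1:03d}"] = v
        for i, v in enumerate(s.phase_deg):
            row[f"phase_{i + 1:03d}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FORMAT)
    _sidecar(path).write_text(
        json.dumps({"frequencies_hz": [float(f) for f in grid.frequencies]})
    )


def read_spectra_csv(path) -> List[ImpedanceSpectrum]:
    path = Path(path)
    grid = FrequencyGrid(
        np.asarray(json.loads(_sidecar(path).read_text())["frequencies_hz"])
    )
    df = pd.read_csv(path)
    n = len(grid)
    zcols = [f"zmod_{i + 1:03d}" for i in range(n)]
    pcols = [f"phase_{i + 1:03d}" for i in range(n)]
    out = []
    for _, row in df.iterrows():
        values = from_polar(row[zcols].to_numpy(float), row[pcols].to_numpy(float))
        out.append(
            ImpedanceSpectrum(
                grid=grid,
                values=values,
                metadata=SpectrumMetadata(
                    sample_id=str(row["sample_id"]),
                    day=int(row["day"]),
                    size=str(row["size"]),
                    storage=str(row["storage"]),
                    diameter_mm=float(row["diameter_mm"]),
                ),
            )
        )
    return out


def write_fits_csv(fits: Sequence[FitResult], path) -> None:
    rows = []
    for r in fits:
        m = r.metadata if r.metadata is not None else SpectrumMetadata()
        row = {"sample_id": m.sample_id, "day": m.day}
        row.update(dict(zip(EC_PARAMETER_NAMES, r.params.as_array())))
        row["chi_square"] = r.chi_square
        row["converged"] = r.converged
        rows.append(row)
    pd.DataFrame(rows).to_csv(Path(path), index=False, float_format=FLOAT_FORMAT)


def write_truth_csv(records: Sequence[SampleRecord], path) -> None:
    """Per-fruit latent parameters by day, for recovery checks."""
    rows = []
    for rec in records:
        for day, params in sorted(rec.true_params.items()):
            row = {
                "sample_id": rec.sample_id,
                "day": day,
                "size": rec.size,
                "storage": rec.storage,
                "diameter_mm": rec.diameter_mm,
            }
            row.update(dict(zip(EC_PARAMETER_NAMES, params.as_array())))
            rows.append(row)
    pd.DataFrame(rows).to_csv(Path(path), index=False, float_format=FLOAT_FORMAT)


def write_feature_table(table: FeatureTable, path, extra: Dict | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame(table.X, columns=list(table.feature_names))
    df.insert(0, "instance_id", list(table.instance_ids))
    df["storage"] = table.y
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    meta = {
        "kind": table.kind,
        "feature_names": list(table.feature_names),
        "n_instances": table.n_instances,
    }
    if extra:
        meta.update(extra)
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_feature_table(path) -> FeatureTable:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    df = pd.read_csv(path)
    names = meta["feature_names"]
    return FeatureTable(
        kind=meta["kind"],
        instance_ids=tuple(df["instance_id"].astype(str)),
        feature_names=tuple(names),
        X=df[names].to_numpy(float),
        y=df["storage"].to_numpy(),
    )
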