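"""Readers and writers for the plain-text interchange formats.

Spectra travel as two-column CSV (frequency_GHz, counts) with a JSON sidecar
holding the scattering configuration; velocity datasets as CSV with columns
(alpha_deg, branch, c_mps, sigma_c_mps); tensors and fit reports as JSON.
All writers emit RFC-4180 CSV via pandas; readers reject malformed rows with
line-numbered errors.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .christoffel import BranchVelocities, TIElasticTensor
from .errors import ParseError
from .geometry import ScatteringConfig
from .inversion import TensorFitResult, VelocityDatum
from .spectral import PhononPeak, Spectrum


def _read_csv(path, columns) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as e:
        raise ParseError(f"cannot parse CSV: {e}", path=str(path)) from e
    if df.empty:
        raise ParseError("file contains no data rows", path=str(path))
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"missing columns {missing}; found {list(df.columns)}", path=str(path))
    return df


def _require_numeric(df: pd.DataFrame, cols: Sequence[str], path: str) -> pd.DataFrame:
    for c in cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna() | df[c].isna()
        if bad.any():
            # +2: one for the header, one for 1-based numbering
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ParseError(f"non-numeric value in column {c!r}", path=path, line=line)
        df[c] = coerced
    return df


# -- spectra -----------------------------------------------------------------

def write_spectrum(spectrum: Spectrum, csv_path, sidecar_path=None) -> None:
    csv_path = Path(csv_path)
    pd.DataFrame(
        {"frequency_GHz": spectrum.frequency_ghz, "counts": spectrum.intensity}
    ).to_csv(csv_path, index=False, float_format="%.17g")
    sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    sidecar.write_text(json.dumps(spectrum.config.to_dict(), indent=1) + "\n")


def read_spectrum(csv_path, sidecar_path=None) -> Spectrum:
    csv_path = Path(csv_path)
    df = _read_csv(csv_path, ["frequency_GHz", "counts"])
    df = _require_numeric(df, ["frequency_GHz", "counts"], str(csv_path))
    sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    if not sidecar.exists():
        raise ParseError("spectrum sidecar JSON with the scattering config not found", path=str(sidecar))
    config = ScatteringConfig.from_dict(json.loads(sidecar.read_text()))
    return Spectrum(
        frequency_ghz=df["frequency_GHz"].to_numpy(),
        intensity=df["counts"].to_numpy(),
        config=config,
    )


# -- peak tables -------------------------------------------------------------

def write_peak_table(peaks: Sequence[PhononPeak], path) -> None:
    pd.DataFrame(
        [
            {
                "branch": p.branch,
                "f_GHz": p.center_f,
                "sigma_f_GHz": p.sigma_f,
                "fwhm_GHz": p.fwhm,
                "amplitude": p.amplitude,
            }
            for p in peaks
        ]
    ).to_csv(path, index=False, float_format="%.17g")


# -- velocity tables ---------------------------------------------------------

VELOCITY_COLUMNS = ("alpha_deg", "branch", "c_mps", "sigma_c_mps")


def write_velocity_table(data: Sequence[VelocityDatum], path) -> None:
    pd.DataFrame(
        [
            {"alpha_deg": d.alpha_deg, "branch": d.branch, "c_mps": d.c, "sigma_c_mps": d.sigma_c}
            for d in data
        ]
    ).to_csv(path, index=False, float_format="%.17g")


def read_velocity_table(path) -> list[VelocityDatum]:
    path = str(path)
    df = _read_csv(path, VELOCITY_COLUMNS)
    df = _require_numeric(df, ["alpha_deg", "c_mps", "sigma_c_mps"], path)
    data = []
    for i, row in df.iterrows():
        try:
            data.append(
                VelocityDatum(
                    alpha_deg=float(row["alpha_deg"]),
                    branch=str(row["branch"]),
                    c=float(row["c_mps"]),
                    sigma_c=float(row["sigma_c_mps"]),
                )
            )
        except Exception as e:
            raise ParseError(str(e), path=path, line=int(i) + 2) from e
    return data


# -- tensors, curves, reports ------------------------------------------------

def write_tensor(tensor: TIElasticTensor, path) -> None:
    Path(path).write_text(json.dumps(tensor.as_dict(), indent=1) + "\n")


def read_tensor(path) -> TIElasticTensor:
    try:
        return TIElasticTensor.from_dict(json.loads(Path(path).read_text()))
    except (KeyError, ValueError, TypeError) as e:
        raise ParseError(f"invalid tensor JSON: {e}", path=str(path)) from e


def write_velocity_curves(bv: BranchVelocities, path) -> None:
    pd.DataFrame(
        {
            "alpha_deg": np.atleast_1d(bv.alpha_deg),
            "c_QL": np.atleast_1d(bv.c_QL),
            "c_QT": np.atleast_1d(bv.c_QT),
            "c_PT": np.atleast_1d(bv.c_PT),
        }
    ).to_csv(path, index=False, float_format="%.17g")


def write_fit_report(result: TensorFitResult, path, moduli: dict | None = None) -> None:
    report = result.report()
    if moduli is not None:
        report["engineering_moduli_GPa"] = moduli
    Path(path).write_text(json.dumps(report, indent=1) + "\n")


def load_config_file(path) -> dict:
    """Load an analysis configuration from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix in (".yaml", ".yml"):
            return yaml.safe_load(text)
        return json.loads(text)
    except Exception as e:
        raise ParseError(f"cannot parse config: {e}", path=str(path)) from e
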