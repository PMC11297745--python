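"""Plain-text readers/writers and run configuration.

All artifacts are column-documented text tables (losslessly round-trippable at
12 significant digits): schemes as 1-based ``A B M N`` rows, datasets with
``A B M N frequency_Hz magnitude_Ohm phase_mrad K``, fields as
``cell magnitude_Ohmm phase_mrad``, masks as polygon vertex lists.  Every
writer stamps a header with the run seed and a configuration hash so outputs
are traceable to the run that produced them.
"""

from __future__ import annotations

import hashlib
import io as _io
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .forward import MRAD, ComplexDataset, MeasurementScheme, Quadrupole
from .geometry import TriMesh

__all__ = [
    "RunConfig",
    "write_scheme",
    "read_scheme",
    "write_dataset",
    "read_dataset",
    "write_field_table",
    "read_field_table",
    "write_polygon",
    "read_polygon",
]

FLOAT_FMT = "%.12g"


@dataclass
class RunConfig:
    """Configuration of one pipeline run (serialized as YAML)."""

    seed: int = 0
    base_cell: float = 0.02
    refinement_level: float = 0.25
    frequency_band: tuple[float, float] = (0.79, 1000.0)
    error_a: float = 0.01
    error_b: float = 0.001
    error_c: float = 0.5
    target_size: int = 800
    dipole_budget: int = 40
    debye_points_per_decade: int = 20
    debye_regularization: float = 0.05
    scheme_path: str | None = None
    mask_path: str | None = None
    output_dir: str = "results"

    def hash(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        data = yaml.safe_load(path.read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "frequency_band" in data:
            data["frequency_band"] = tuple(data["frequency_band"])
        return cls(**data)


def _header(kind: str, config: RunConfig | None, seed: int | None) -> str:
    bits = [f"# rhizoseit {kind}"]
    if config is not None:
        bits.append(f"# config_hash: {config.hash()}")
        seed = config.seed if seed is None else seed
    if seed is not None:
        bits.append(f"# seed: {seed}")
    return "\n".join(bits) + "\n"


def _write_table(df: pd.DataFrame, path: Path, kind: str, config, seed) -> None:
    buf = _io.StringIO()
    df.to_csv(buf, index=False, float_format=FLOAT_FMT)
    path.write_text(_header(kind, config, seed) + buf.getvalue())


def _read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_scheme(
    scheme: MeasurementScheme, path: str | Path, config: RunConfig | None = None,
    seed: int | None = None,
) -> None:
    """Write a scheme as 1-based A,B,M,N rows."""
    df = pd.DataFrame(scheme.abmn + 1, columns=["A", "B", "M", "N"])
    _write_table(df, Path(path), "scheme", config, seed)


def read_scheme(path: str | Path) -> MeasurementScheme:
    df = _read_table(path)
    return MeasurementScheme(
        [Quadrupole(*(int(v) - 1 for v in row)) for row in df[["A", "B", "M", "N"]].to_numpy()]
    )


def write_dataset(
    dataset: ComplexDataset, path: str | Path, config: RunConfig | None = None,
    seed: int | None = None,
) -> None:
    rows = []
    abmn = dataset.scheme.abmn + 1
    k = dataset.k if dataset.k is not None else np.full(len(dataset.scheme), np.nan)
    for i in range(len(dataset.scheme)):
        for j, f in enumerate(dataset.frequencies):
            rows.append(
                [*abmn[i], f, abs(dataset.z[i, j]), np.angle(dataset.z[i, j]) / MRAD, k[i]]
            )
    df = pd.DataFrame(
        rows, columns=["A", "B", "M", "N", "frequency_Hz", "magnitude_Ohm", "phase_mrad", "K"]
    )
    _write_table(df, Path(path), "dataset", config, seed)


def read_dataset(path: str | Path) -> ComplexDataset:
    df = _read_table(path)
    quads = df[["A", "B", "M", "N"]].drop_duplicates().to_numpy()
    scheme = MeasurementScheme([Quadrupole(*(int(v) - 1 for v in q)) for q in quads])
    freqs = np.sort(df["frequency_Hz"].unique())
    z = np.empty((len(scheme), len(freqs)), complex)
    k = np.full(len(scheme), np.nan)
    index = {tuple(q): i for i, q in enumerate(quads)}
    findex = {f: j for j, f in enumerate(freqs)}
    for row in df.itertuples(index=False):
        i = index[(row.A, row.B, row.M, row.N)]
        z[i, findex[row.frequency_Hz]] = row.magnitude_Ohm * np.exp(1j * MRAD * row.phase_mrad)
        k[i] = row.K
    return ComplexDataset(scheme, freqs, z, None if np.isnan(k).all() else k)


def write_field_table(
    magnitude: np.ndarray, phase_mrad: np.ndarray, path: str | Path,
    config: RunConfig | None = None, seed: int | None = None,
) -> None:
    """Per-cell field image: cell id, |rho*| (Ohm m), phase (mrad)."""
    df = pd.DataFrame(
        {
            "cell": np.arange(len(magnitude)),
            "magnitude_Ohmm": np.asarray(magnitude, float),
            "phase_mrad": np.asarray(phase_mrad, float),
        }
    )
    _write_table(df, Path(path), "field", config, seed)


def read_field_table(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = _read_table(path)
    return df["magnitude_Ohmm"].to_numpy(), df["phase_mrad"].to_numpy()


def write_polygon(vertices: np.ndarray, path: str | Path) -> None:
    """Root-zone outline as an x,y vertex list (m)."""
    df = pd.DataFrame(np.asarray(vertices, float), columns=["x_m", "y_m"])
    _write_table(df, Path(path), "polygon", None, None)


def read_polygon(path: str | Path) -> np.ndarray:
    df = _read_table(path)
    return df[["x_m", "y_m"]].to_numpy()
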