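"""Station geometry, tabular I/O and run configuration.

All tabular files are UTF-8 text with one header row and ``.`` as decimal
separator; metadata travels in ``# key=value`` comment lines above the
header.  Depth coordinates are millimetres below the sediment-water (or
chip-water) interface, positive downward.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import logging
import re
from dataclasses import dataclass, field
from datetime import date
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("woodfall")

EARTH_RADIUS_M = 6_371_000.0

_DDM_RE = re.compile(
    r"^\s*(?P<hemi>[NSEW])\s*(?P<deg>\d+)\s*[°d]\s*(?P<minutes>\d+(?:\.\d+)?)\s*['′]?\s*$"
)


class CoordinateParseError(ValueError):
    """Raised when a degrees-decimal-minutes string cannot be parsed."""


def parse_ddm(coord_text: str) -> float:
    """Parse a degrees + decimal-minutes coordinate to decimal degrees.

    Parameters
    ----------
    coord_text : str
        e.g. ``"N 32°32.0496"`` or ``"S 10°30.0"``.

    Returns
    -------
    float
        Decimal degrees, negative for S/W hemispheres.
    """
    m = _DDM_RE.match(coord_text)
    if m is None:
        raise CoordinateParseError(
            f"cannot parse degrees-decimal-minutes coordinate: {coord_text!r}"
        )
    hemi = m.group("hemi")
    deg = int(m.group("deg"))
    minutes = float(m.group("minutes"))
    if not 0.0 <= minutes < 60.0:
        raise CoordinateParseError(
            f"minutes out of range [0, 60) in {coord_text!r}: {minutes}"
        )
    limit = 90 if hemi in "NS" else 180
    if deg > limit or (deg == limit and minutes > 0):
        raise CoordinateParseError(
            f"degrees out of range for hemisphere {hemi!r} in {coord_text!r}: {deg}"
        )
    value = deg + minutes / 60.0
    if hemi in "SW":
        value = -value
    return value


@dataclass(frozen=True)
class Station:
    """A deployment position with degrees + decimal-minutes coordinates."""

    id: str
    location: str
    latitude_deg: int
    latitude_min: float
    latitude_hemisphere: str
    longitude_deg: int
    longitude_min: float
    longitude_hemisphere: str
    deployed: date | None = None
    recovered: date | None = None

    def __post_init__(self) -> None:
        for minutes, label in (
            (self.latitude_min, "latitude"),
            (self.longitude_min, "longitude"),
        ):
            if not 0.0 <= minutes < 60.0:
                raise ValueError(f"{label} minutes out of range [0, 60): {minutes}")
        if self.latitude_hemisphere not in ("N", "S"):
            raise ValueError(f"bad latitude hemisphere: {self.latitude_hemisphere!r}")
        if self.longitude_hemisphere not in ("E", "W"):
            raise ValueError(f"bad longitude hemisphere: {self.longitude_hemisphere!r}")
        if self.latitude_deg > 90 or (self.latitude_deg == 90 and self.latitude_min > 0):
            raise ValueError(f"latitude degrees out of range: {self.latitude_deg}")
        if self.longitude_deg > 180 or (
            self.longitude_deg == 180 and self.longitude_min > 0
        ):
            raise ValueError(f"longitude degrees out of range: {self.longitude_deg}")
        if self.deployed is not None and self.recovered is not None:
            if self.recovered < self.deployed:
                raise ValueError(
                    f"recovered ({self.recovered}) before deployed ({self.deployed})"
                )

    @classmethod
    def from_position(
        cls,
        id: str,
        position: str,
        location: str = "",
        deployed: date | None = None,
        recovered: date | None = None,
    ) -> "Station":
        """Build a station from a combined position string like
        ``"N 32°32.0496 E 30°21.1248"``."""
        parts = re.findall(r"[NSEW]\s*\d+\s*[°d]\s*\d+(?:\.\d+)?['′]?", position)
        if len(parts) != 2:
            raise CoordinateParseError(f"cannot split position string: {position!r}")
        lat_txt, lon_txt = parts
        if lat_txt.lstrip()[0] in "EW":
            lat_txt, lon_txt = lon_txt, lat_txt
        lat_m = _DDM_RE.match(lat_txt)
        lon_m = _DDM_RE.match(lon_txt)
        assert lat_m is not None and lon_m is not None
        # validate through parse_ddm so range errors share one code path
        parse_ddm(lat_txt)
        parse_ddm(lon_txt)
        return cls(
            id=id,
            location=location,
            latitude_deg=int(lat_m.group("deg")),
            latitude_min=float(lat_m.group("minutes")),
            latitude_hemisphere=lat_m.group("hemi"),
            longitude_deg=int(lon_m.group("deg")),
            longitude_min=float(lon_m.group("minutes")),
            longitude_hemisphere=lon_m.group("hemi"),
            deployed=deployed,
            recovered=recovered,
        )

    @property
    def latitude(self) -> float:
        sign = -1.0 if self.latitude_hemisphere == "S" else 1.0
        return sign * (self.latitude_deg + self.latitude_min / 60.0)

    @property
    def longitude(self) -> float:
        sign = -1.0 if self.longitude_hemisphere == "W" else 1.0
        return sign * (self.longitude_deg + self.longitude_min / 60.0)


def haversine_m(
    lat1: float, lon1: float, lat2: float, lon2: float, radius_m: float = EARTH_RADIUS_M
) -> float:
    """Great-circle distance in metres on a sphere."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return float(2.0 * radius_m * np.arcsin(np.sqrt(a)))


def station_distance(a: Station, b: Station) -> float:
    """Great-circle separation of two stations in metres (R = 6371 km)."""
    return haversine_m(a.latitude, a.longitude, b.latitude, b.longitude)


# ---------------------------------------------------------------------------
# Tabular I/O


def read_table(path: str | Path, sep: str = "\t") -> tuple[pd.DataFrame, dict]:
    """Read a headered table, collecting ``# key=value`` metadata lines."""
    path = Path(path)
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line[1:].strip()
                if "=" in stripped:
                    key, _, value = stripped.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            body_lines.append(line)
    df = pd.read_csv(io.StringIO("".join(body_lines)), sep=sep)
    return df, meta


def write_table(
    df: pd.DataFrame, path: str | Path, meta: dict | None = None, sep: str = "\t"
) -> None:
    """Write a table with optional ``# key=value`` metadata header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep=sep, index=False, lineterminator="\n")


def file_digest(path: str | Path) -> str:
    """SHA-256 hex digest of a file, for replayable-run logging."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """All tunable parameters with their published defaults.

    Every value can be overridden from a flat YAML file; ``config_hash``
    identifies the effective parameter set in logs.
    """

    # diffusion coefficients in sediment, m^2 s^-1
    d_sed_o2: float = 8.9e-10
    d_sed_sulfide: float = 6.4e-10
    d_sed_doc: float = 6.2e-11
    # porosities per matrix
    porosity_sediment: float = 0.65
    porosity_wood_chips: float = 0.95
    # sulfide first dissociation constant (seawater, study T/S)
    pk1: float = 6.98
    # gradient extraction
    gradient_window: int = 3
    detection_limit_uM: float = 1.0
    # chamber fitting
    chamber_r2_min: float = 0.98
    chamber_min_points: int = 10
    chamber_area_cm2: float = 284.0
    # radiotracer
    fractionation_factor_sr: float = 1.06
    fractionation_factor_aom: float = 1.0
    # fingerprint binning
    bin_size_bp: float = 2.0
    size_range_low_bp: float = 100.0
    size_range_high_bp: float = 1000.0
    replicate_min_present: int = 1
    # community statistics
    n_resample: int = 1000
    n_permutations: int = 999
    nmds_starts: int = 20
    # carbon budget
    molar_mass_c: float = 12.011
    respiratory_quotient: float = 1.0
    # randomness
    seed: int | None = None

    def d_sed(self, analyte: str) -> float:
        table = {
            "O2": self.d_sed_o2,
            "H2S": self.d_sed_sulfide,
            "totalS": self.d_sed_sulfide,
            "DOC": self.d_sed_doc,
        }
        try:
            return table[analyte]
        except KeyError:
            raise KeyError(f"no default diffusion coefficient for analyte {analyte!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True),
            encoding="utf-8",
        )

    @property
    def config_hash(self) -> str:
        payload = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode("utf-8")).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Packaged station fixture


def load_stations(path: str | Path | None = None) -> dict[str, Station]:
    """Load the deployment-station fixture (or a user-supplied table).

    The table needs columns ``id``, ``location``, ``position``,
    ``deployed``, ``recovered``.
    """
    if path is None:
        source = resources.files("woodfall.data").joinpath("stations.tsv")
        text = source.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    df = pd.read_csv(io.StringIO(text), sep="\t", comment="#")
    stations: dict[str, Station] = {}
    for row in df.itertuples(index=False):
        stations[row.id] = Station.from_position(
            id=row.id,
            position=row.position,
            location=row.location,
            deployed=date.fromisoformat(row.deployed),
            recovered=date.fromisoformat(row.recovered),
        )
    return stations


def log_stage(stage: str, config: RunConfig, inputs: Iterable[str | Path] = ()) -> None:
    """Log a pipeline stage with its config hash and input digests."""
    digests = {str(p): file_digest(p) for p in inputs}
    logger.info("stage=%s config=%s inputs=%s", stage, config.config_hash, digests)
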