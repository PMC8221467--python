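"""Landmark dataset containers and plain-text readers/writers.

Four dialects are supported: CSV (one header row, one specimen per row
with inline metadata), WHITESPACE (bare coordinate tables, wide or long
layout, metadata joined from a side file), TPS (``LM3=k`` blocks) and
Morphologika (``[individuals]`` / ``[rawpoints]`` sections).  All formats
are uncompressed text; coordinates are stored as millimetres but treated
as unitless downstream because Procrustes superimposition removes scale.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class Group(str, Enum):
    """Skeletal population groups of the four-group study design."""

    EARLY_AS = "EARLY_AS"
    MIDDLE_AS = "MIDDLE_AS"
    PREMED_BRITISH = "PREMED_BRITISH"
    DANISH = "DANISH"


class Sex(str, Enum):
    F = "F"
    M = "M"


class Role(str, Enum):
    """Whether a group serves as a known ancestry source or an attribution target."""

    SOURCE = "SOURCE"
    TARGET = "TARGET"


SOURCE_GROUPS = (Group.PREMED_BRITISH, Group.DANISH)
TARGET_GROUPS = (Group.EARLY_AS, Group.MIDDLE_AS)


def role_of(group: Group) -> Role:
    return Role.SOURCE if Group(group) in SOURCE_GROUPS else Role.TARGET


class Dialect(str, Enum):
    CSV = "CSV"
    WHITESPACE = "WHITESPACE"
    TPS = "TPS"
    MORPHOLOGIKA = "MORPHOLOGIKA"


def _as_dialect(d) -> "Dialect":
    return d if isinstance(d, Dialect) else Dialect(str(d).upper())


class LandmarkValidationError(ValueError):
    """Raised when a configuration or dataset violates its structural invariants."""


@dataclass
class LandmarkConfiguration:
    """One specimen's k x 3 Cartesian landmark matrix with ordered labels."""

    specimen_id: str
    coords: np.ndarray
    landmark_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise LandmarkValidationError(
                f"specimen {self.specimen_id!r}: coords must be k x 3, got {self.coords.shape}"
            )
        if self.coords.shape[0] < 3:
            raise LandmarkValidationError(
                f"specimen {self.specimen_id!r}: need at least 3 landmarks"
            )
        if not np.all(np.isfinite(self.coords)):
            raise LandmarkValidationError(
                f"specimen {self.specimen_id!r}: missing or non-finite coordinates"
            )
        if not self.landmark_labels:
            self.landmark_labels = [f"lm{i + 1}" for i in range(self.coords.shape[0])]
        if len(self.landmark_labels) != self.coords.shape[0]:
            raise LandmarkValidationError(
                f"specimen {self.specimen_id!r}: {len(self.landmark_labels)} labels "
                f"for {self.coords.shape[0]} landmarks"
            )
        if len(set(self.landmark_labels)) != len(self.landmark_labels):
            raise LandmarkValidationError(
                f"specimen {self.specimen_id!r}: landmark labels not unique"
            )

    @property
    def k(self) -> int:
        return self.coords.shape[0]


@dataclass
class SpecimenMetadata:
    specimen_id: str
    group: Group
    sex: Sex
    site: str | None = None

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        self.sex = Sex(self.sex)

    @property
    def role(self) -> Role:
        return role_of(self.group)


@dataclass
class ShapeDataset:
    """An ordered collection of same-k configurations with matching metadata."""

    configurations: list[LandmarkConfiguration]
    metadata: list[SpecimenMetadata] = field(default_factory=list)
    scheme: "object | None" = None  # SymmetryScheme; untyped to avoid a cycle

    def __post_init__(self) -> None:
        if not self.configurations:
            return
        k0 = self.configurations[0].k
        labels0 = self.configurations[0].landmark_labels
        for c in self.configurations:
            if c.k != k0:
                raise LandmarkValidationError(
                    f"specimen {c.specimen_id!r} has {c.k} landmarks, expected {k0}"
                )
            if c.landmark_labels != labels0:
                raise LandmarkValidationError(
                    f"specimen {c.specimen_id!r} has a different landmark label order"
                )
        ids = [c.specimen_id for c in self.configurations]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise LandmarkValidationError(f"duplicate specimen ids: {dup}")
        if self.metadata:
            meta_ids = {m.specimen_id for m in self.metadata}
            if len(self.metadata) != len(self.configurations) or meta_ids != set(ids):
                missing = sorted(set(ids) - meta_ids)
                extra = sorted(meta_ids - set(ids))
                raise LandmarkValidationError(
                    f"metadata does not match configurations (missing {missing}, unknown {extra})"
                )
            order = {sid: i for i, sid in enumerate(ids)}
            self.metadata = sorted(self.metadata, key=lambda m: order[m.specimen_id])

    def __len__(self) -> int:
        return len(self.configurations)

    @property
    def n_specimens(self) -> int:
        return len(self.configurations)

    @property
    def k(self) -> int:
        return self.configurations[0].k if self.configurations else 0

    @property
    def landmark_labels(self) -> list[str]:
        return self.configurations[0].landmark_labels if self.configurations else []

    def specimen_ids(self) -> list[str]:
        return [c.specimen_id for c in self.configurations]

    def coords_array(self) -> np.ndarray:
        """Stack coordinates into an (n, k, 3) array."""
        return np.stack([c.coords for c in self.configurations])

    def groups(self) -> np.ndarray:
        self._require_metadata()
        return np.array([m.group.value for m in self.metadata])

    def sexes(self) -> np.ndarray:
        self._require_metadata()
        return np.array([m.sex.value for m in self.metadata])

    def _require_metadata(self) -> None:
        if not self.metadata:
            raise LandmarkValidationError("dataset has no metadata")

    def with_coords(self, coords: np.ndarray) -> "ShapeDataset":
        """Copy of the dataset with every specimen's coordinates replaced."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_specimens, self.k, 3):
            raise LandmarkValidationError(
                f"replacement coords shape {coords.shape} != {(self.n_specimens, self.k, 3)}"
            )
        configs = [
            LandmarkConfiguration(c.specimen_id, coords[i], list(c.landmark_labels))
            for i, c in enumerate(self.configurations)
        ]
        return ShapeDataset(configs, list(self.metadata), self.scheme)

    def subset(
        self,
        sex: Sex | str | None = None,
        groups: Iterable[Group | str] | None = None,
    ) -> "ShapeDataset":
        """Select specimens by sex and/or group, preserving original order."""
        if sex is None and groups is None:
            return ShapeDataset(list(self.configurations), list(self.metadata), self.scheme)
        self._require_metadata()
        want_groups = None
        if groups is not None:
            want_groups = {Group(g) for g in groups}
            known = {m.group for m in self.metadata}
            unknown = want_groups - known
            if unknown:
                raise LandmarkValidationError(
                    f"requested groups not present: {sorted(g.value for g in unknown)}"
                )
        want_sex = Sex(sex) if sex is not None else None
        keep = [
            i
            for i, m in enumerate(self.metadata)
            if (want_sex is None or m.sex == want_sex)
            and (want_groups is None or m.group in want_groups)
        ]
        if not keep:
            warnings.warn("subset matched no specimens", stacklevel=2)
        return ShapeDataset(
            [self.configurations[i] for i in keep],
            [self.metadata[i] for i in keep],
            self.scheme,
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide table: one row per specimen, metadata + flat coordinates."""
        rows = []
        for c, m in zip(self.configurations, self.metadata or [None] * len(self)):
            row = {"specimen_id": c.specimen_id}
            if m is not None:
                row["group"] = m.group.value
                row["sex"] = m.sex.value
                if m.site:
                    row["site"] = m.site
            for lab, (x, y, z) in zip(c.landmark_labels, c.coords):
                row[f"{lab}_x"] = x
                row[f"{lab}_y"] = y
                row[f"{lab}_z"] = z
            rows.append(row)
        return pd.DataFrame(rows)


def subset(dataset: ShapeDataset, sex=None, groups=None) -> ShapeDataset:
    """Functional alias of :meth:`ShapeDataset.subset`."""
    return dataset.subset(sex=sex, groups=groups)


# ---------------------------------------------------------------------------
# readers


def read_landmarks(
    path: str | Path,
    dialect: Dialect | str = Dialect.CSV,
    metadata_path: str | Path | None = None,
    layout: str = "wide",
) -> ShapeDataset:
    """Read a landmark dataset in the declared dialect.

    Parameters
    ----------
    path : path to the coordinate file.
    dialect : CSV, WHITESPACE, TPS or MORPHOLOGIKA.
    metadata_path : optional CSV with columns specimen_id, group, sex[, site],
        joined by specimen_id.  The CSV dialect carries metadata inline and
        ignores this argument unless given.
    layout : for CSV/WHITESPACE, "wide" (one row per specimen) or "long"
        (one row per landmark with a specimen_id column).
    """
    dialect = _as_dialect(dialect)
    path = Path(path)
    if dialect is Dialect.CSV:
        ds = _read_delimited(path, layout=layout, delimiter=",")
    elif dialect is Dialect.WHITESPACE:
        ds = _read_delimited(path, layout=layout, delimiter=None)
    elif dialect is Dialect.TPS:
        ds = _read_tps(path)
    else:
        ds = _read_morphologika(path)
    if metadata_path is not None:
        meta = read_metadata(metadata_path)
        ds = _join_metadata(ds, meta)
    return ds


def read_metadata(path: str | Path) -> list[SpecimenMetadata]:
    df = pd.read_csv(path, dtype=str)
    required = {"specimen_id", "group", "sex"}
    if not required.issubset(df.columns):
        raise LandmarkValidationError(
            f"metadata file {path} must have columns {sorted(required)}"
        )
    return [
        SpecimenMetadata(
            specimen_id=r["specimen_id"],
            group=Group(r["group"]),
            sex=Sex(r["sex"]),
            site=r.get("site") if isinstance(r.get("site"), str) else None,
        )
        for r in df.to_dict("records")
    ]


def _join_metadata(ds: ShapeDataset, meta: list[SpecimenMetadata]) -> ShapeDataset:
    by_id = {m.specimen_id: m for m in meta}
    matched = []
    for c in ds.configurations:
        if c.specimen_id not in by_id:
            raise LandmarkValidationError(
                f"specimen {c.specimen_id!r} missing from metadata file"
            )
        matched.append(by_id[c.specimen_id])
    return ShapeDataset(ds.configurations, matched, ds.scheme)


_META_COLS = ("specimen_id", "group", "sex", "site")


def _sniff_delimiter(text: str) -> str | None:
    first = text.splitlines()[0] if text else ""
    for cand in (",", "\t", ";"):
        if cand in first:
            return cand
    return None  # whitespace split


def _read_delimited(path: Path, layout: str, delimiter: str | None) -> ShapeDataset:
    text = Path(path).read_text()
    if delimiter is None:
        delimiter = _sniff_delimiter(text)
    if layout == "long":
        return _read_long(path, delimiter)
    sep = delimiter if delimiter is not None else r"\s+"
    df = pd.read_csv(path, sep=sep, engine="python")
    # headerless if the would-be header row contains numeric tokens
    headerless = any(_looks_numeric(str(c)) for c in df.columns)
    if headerless:
        df = pd.read_csv(path, sep=sep, engine="python", header=None)
        df = df.rename(columns={0: "specimen_id"})
        df["specimen_id"] = df["specimen_id"].astype(str)
    cols = [str(c) for c in df.columns]
    meta_present = "group" in cols and "sex" in cols
    coord_cols = [c for c in df.columns if str(c) not in _META_COLS]
    ncoord = len(coord_cols)
    if ncoord % 3 != 0:
        raise LandmarkValidationError(
            f"{path}: {ncoord} coordinate columns is not a multiple of 3"
        )
    k = ncoord // 3
    labels = _labels_from_columns([str(c) for c in coord_cols], k)
    configs, meta = [], []
    for _, row in df.iterrows():
        sid = str(row["specimen_id"]) if "specimen_id" in df.columns else str(row.iloc[0])
        vals = row[coord_cols].to_numpy(dtype=float)
        configs.append(LandmarkConfiguration(sid, vals.reshape(k, 3), list(labels)))
        if meta_present:
            site = row.get("site")
            meta.append(
                SpecimenMetadata(
                    sid,
                    Group(str(row["group"])),
                    Sex(str(row["sex"])),
                    site=str(site) if isinstance(site, str) else None,
                )
            )
    return ShapeDataset(configs, meta)


def _looks_numeric(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def _labels_from_columns(cols: Sequence[str], k: int) -> list[str]:
    # header like lm1_x,lm1_y,lm1_z -> labels lm1..lmk; otherwise default labels
    stems = []
    for c in cols[0::3]:
        m = re.match(r"(.+)_x$", c)
        if not m:
            return [f"lm{i + 1}" for i in range(k)]
        stems.append(m.group(1))
    return stems


def _read_long(path: Path, delimiter: str | None) -> ShapeDataset:
    sep = delimiter if delimiter is not None else r"\s+"
    df = pd.read_csv(path, sep=sep, engine="python")
    need = {"specimen_id", "x", "y", "z"}
    if not need.issubset({str(c) for c in df.columns}):
        raise LandmarkValidationError(
            f"{path}: long layout needs columns specimen_id,[landmark,]x,y,z"
        )
    configs = []
    k_ref: int | None = None
    for sid, grp in df.groupby("specimen_id", sort=False):
        coords = grp[["x", "y", "z"]].to_numpy(dtype=float)
        labels = (
            [str(v) for v in grp["landmark"]]
            if "landmark" in grp.columns
            else [f"lm{i + 1}" for i in range(len(grp))]
        )
        if k_ref is None:
            k_ref = len(grp)
        elif len(grp) != k_ref:
            raise LandmarkValidationError(
                f"specimen {sid!r} has {len(grp)} landmarks, expected {k_ref}"
            )
        configs.append(LandmarkConfiguration(str(sid), coords, labels))
    return ShapeDataset(configs, [])


def _read_tps(path: Path) -> ShapeDataset:
    configs = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        m = re.match(r"LM3\s*=\s*(\d+)", line, flags=re.IGNORECASE)
        if not m:
            raise LandmarkValidationError(f"{path}: expected 'LM3=k' block, got {line!r}")
        k = int(m.group(1))
        coords = np.empty((k, 3))
        for j in range(k):
            parts = lines[i].split()
            if len(parts) != 3:
                raise LandmarkValidationError(
                    f"{path}: landmark row {j + 1} has {len(parts)} values, expected 3"
                )
            coords[j] = [float(p) for p in parts]
            i += 1
        sid = None
        while i < len(lines) and lines[i].strip():
            key_line = lines[i].strip()
            i += 1
            mid = re.match(r"ID\s*=\s*(.+)", key_line, flags=re.IGNORECASE)
            if mid:
                sid = mid.group(1).strip()
                break
        if sid is None:
            sid = f"specimen{len(configs) + 1}"
        configs.append(LandmarkConfiguration(sid, coords))
    return ShapeDataset(configs, [])


def _read_morphologika(path: Path) -> ShapeDataset:
    text = Path(path).read_text()
    sections: dict[str, list[str]] = {}
    current = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        m = re.match(r"\[(\w+)\]", line)
        if m:
            current = m.group(1).lower()
            sections[current] = []
        elif current is not None:
            sections[current].append(line)
    for need in ("individuals", "landmarks", "dimensions", "rawpoints"):
        if need not in sections:
            raise LandmarkValidationError(f"{path}: missing [{need}] section")
    n = int(sections["individuals"][0])
    k = int(sections["landmarks"][0])
    dims = int(sections["dimensions"][0])
    if dims != 3:
        raise LandmarkValidationError(f"{path}: only 3D data supported, got [dimensions] {dims}")
    names = sections.get("names", [])
    raw = sections["rawpoints"]
    configs = []
    i = 0
    idx = 0
    while i < len(raw):
        line = raw[i]
        if line.startswith("'"):
            sid = line.lstrip("'").strip()
            i += 1
        else:
            sid = names[idx] if idx < len(names) else f"specimen{idx + 1}"
        coords = np.empty((k, 3))
        for j in range(k):
            parts = raw[i].split()
            coords[j] = [float(p) for p in parts[:3]]
            i += 1
        configs.append(LandmarkConfiguration(sid, coords))
        idx += 1
    if len(configs) != n:
        raise LandmarkValidationError(
            f"{path}: [individuals] says {n} but found {len(configs)} point blocks"
        )
    return ShapeDataset(configs, [])


# ---------------------------------------------------------------------------
# writers


def write_landmarks(
    dataset: ShapeDataset,
    path: str | Path,
    dialect: Dialect | str = Dialect.CSV,
    metadata_path: str | Path | None = None,
    precision: int = 10,
) -> None:
    """Write a dataset in the declared dialect (round-trips with read_landmarks)."""
    dialect = _as_dialect(dialect)
    path = Path(path)
    fmt = f"{{:.{precision}g}}"
    if dialect is Dialect.CSV:
        _write_csv(dataset, path, fmt)
    elif dialect is Dialect.WHITESPACE:
        _write_whitespace(dataset, path, fmt)
    elif dialect is Dialect.TPS:
        _write_tps(dataset, path, fmt)
    else:
        _write_morphologika(dataset, path, fmt)
    if metadata_path is not None:
        write_metadata(dataset, metadata_path)


def write_metadata(dataset: ShapeDataset, path: str | Path) -> None:
    dataset._require_metadata()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["specimen_id", "group", "sex", "site"])
        for m in dataset.metadata:
            w.writerow([m.specimen_id, m.group.value, m.sex.value, m.site or ""])


def _write_csv(ds: ShapeDataset, path: Path, fmt: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        header = ["specimen_id"]
        if ds.metadata:
            header += ["group", "sex"]
        for lab in ds.landmark_labels:
            header += [f"{lab}_x", f"{lab}_y", f"{lab}_z"]
        w.writerow(header)
        for i, c in enumerate(ds.configurations):
            row = [c.specimen_id]
            if ds.metadata:
                row += [ds.metadata[i].group.value, ds.metadata[i].sex.value]
            row += [fmt.format(v) for v in c.coords.ravel()]
            w.writerow(row)


def _write_whitespace(ds: ShapeDataset, path: Path, fmt: str) -> None:
    with open(path, "w") as fh:
        for c in ds.configurations:
            vals = " ".join(fmt.format(v) for v in c.coords.ravel())
            fh.write(f"{c.specimen_id} {vals}\n")


def _write_tps(ds: ShapeDataset, path: Path, fmt: str) -> None:
    with open(path, "w") as fh:
        for c in ds.configurations:
            fh.write(f"LM3={c.k}\n")
            for row in c.coords:
                fh.write(" ".join(fmt.format(v) for v in row) + "\n")
            fh.write(f"ID={c.specimen_id}\n")


def _write_morphologika(ds: ShapeDataset, path: Path, fmt: str) -> None:
    with open(path, "w") as fh:
        fh.write("[individuals]\n%d\n" % len(ds))
        fh.write("[landmarks]\n%d\n" % ds.k)
        fh.write("[dimensions]\n3\n")
        fh.write("[names]\n")
        for c in ds.configurations:
            fh.write(c.specimen_id + "\n")
        fh.write("[rawpoints]\n")
        for c in ds.configurations:
            fh.write("'" + c.specimen_id + "\n")
            for row in c.coords:
                fh.write(" ".join(fmt.format(v) for v in row) + "\n")
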