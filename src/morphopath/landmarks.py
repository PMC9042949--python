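"""Landmark and tabular I/O: the tpsDig2 TPS dialect, landmark-role scheme
files, specimen tables and rater-by-stimulus rating matrices.

The TPS dialect handled here is the plain-text one produced by tpsDig2::

    LM=<k>
    <x> <y>          (k coordinate lines, space or tab separated)
    IMAGE=<name>     (optional)
    ID=<id>          (optional)
    SCALE=<s>        (optional; applied multiplicatively to the coordinates)

TPS files carry no landmark roles, so fixed/semi-landmark roles and curve
membership travel in a sidecar *scheme* file with one line per landmark::

    <index> <fixed|semi> <curve_id|->
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SchemaError, TPSParseError

__all__ = [
    "LandmarkConfiguration",
    "LandmarkScheme",
    "read_tps",
    "write_tps",
    "read_scheme",
    "write_scheme",
    "read_specimen_table",
    "write_specimen_table",
    "read_ratings",
]

#: columns a specimen table must provide (bmi may replace weight+height)
REQUIRED_SPECIMEN_COLUMNS = (
    "id", "sex", "age", "L", "a", "b",
    "width1", "width2", "height1", "height2",
)


@dataclass
class LandmarkConfiguration:
    """One specimen's ordered 2-D landmarks in digitising units."""

    specimen_id: str
    points: np.ndarray  # (k, 2)
    scale: float | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError(f"points must be (k, 2), got {self.points.shape}")
        if not np.all(np.isfinite(self.points)):
            raise ValueError(f"non-finite coordinates in specimen {self.specimen_id!r}")

    @property
    def n_landmarks(self) -> int:
        return self.points.shape[0]


@dataclass
class LandmarkScheme:
    """Per-landmark roles (fixed/semi) and curve membership for semi-landmarks.

    Curve members must be consecutive along their curve so that tangents can
    be taken between immediate neighbours when sliding.
    """

    roles: np.ndarray          # (k,) of {"fixed", "semi"}
    curve_ids: np.ndarray      # (k,) object; None for fixed landmarks

    def __post_init__(self):
        self.roles = np.asarray(self.roles, dtype=object)
        self.curve_ids = np.asarray(self.curve_ids, dtype=object)
        if self.roles.shape != self.curve_ids.shape:
            raise ValueError("roles and curve_ids must have equal length")
        bad = set(self.roles) - {"fixed", "semi"}
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}")
        for i, (role, cid) in enumerate(zip(self.roles, self.curve_ids)):
            if role == "semi" and cid is None:
                raise ValueError(f"semi-landmark {i} has no curve id")
        # curve members must be consecutive
        seen_done = set()
        prev = object()
        for cid in self.curve_ids:
            if cid is None:
                prev = None
                continue
            if cid != prev and cid in seen_done:
                raise ValueError(f"curve {cid!r} members are not consecutive")
            if cid != prev:
                seen_done.add(cid)
            prev = cid

    @property
    def n_landmarks(self) -> int:
        return len(self.roles)

    @property
    def n_fixed(self) -> int:
        return int(np.sum(self.roles == "fixed"))

    @property
    def n_semi(self) -> int:
        return int(np.sum(self.roles == "semi"))

    @property
    def semi_indices(self) -> np.ndarray:
        return np.flatnonzero(self.roles == "semi")

    def curve_neighbours(self, j: int) -> tuple[int | None, int | None]:
        """Indices of the previous/next landmark on ``j``'s curve (None at ends)."""
        cid = self.curve_ids[j]
        if cid is None:
            raise ValueError(f"landmark {j} is not a semi-landmark")
        members = [i for i in range(self.n_landmarks) if self.curve_ids[i] == cid]
        pos = members.index(j)
        prev = members[pos - 1] if pos > 0 else None
        nxt = members[pos + 1] if pos < len(members) - 1 else None
        return prev, nxt


def read_tps(path: str | Path) -> list[LandmarkConfiguration]:
    """Parse a TPS file into a list of configurations, order preserved.

    A ``SCALE=`` record is applied multiplicatively to the coordinates of its
    record. An empty file yields an empty list with a warning. A record whose
    coordinate-line count disagrees with its ``LM=`` header raises
    :class:`TPSParseError` naming the record.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    configs: list[LandmarkConfiguration] = []
    i, n_record = 0, 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise TPSParseError(f"record {n_record}: expected 'LM=', got {line!r}")
        try:
            k = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise TPSParseError(f"record {n_record}: bad LM count {line!r}") from exc
        i += 1
        coords = []
        while i < len(lines):
            stripped = lines[i].strip()
            if not stripped or "=" in stripped:
                break
            parts = stripped.replace("\t", " ").split()
            if len(parts) != 2:
                raise TPSParseError(
                    f"record {n_record}: bad coordinate line {lines[i]!r}"
                )
            coords.append((float(parts[0]), float(parts[1])))
            i += 1
        if len(coords) != k:
            raise TPSParseError(
                f"record {n_record}: LM={k} but {len(coords)} coordinate lines"
            )
        image, spec_id, scale = None, None, None
        while i < len(lines):
            stripped = lines[i].strip()
            if not stripped:
                i += 1
                continue
            upper = stripped.upper()
            if upper.startswith("LM="):
                break
            if upper.startswith("IMAGE="):
                image = stripped.split("=", 1)[1]
            elif upper.startswith("ID="):
                spec_id = stripped.split("=", 1)[1]
            elif upper.startswith("SCALE="):
                scale = float(stripped.split("=", 1)[1])
            else:
                raise TPSParseError(f"record {n_record}: unknown line {stripped!r}")
            i += 1
        points = np.asarray(coords, dtype=float)
        if scale is not None:
            points = points * scale
        configs.append(
            LandmarkConfiguration(
                specimen_id=spec_id if spec_id is not None else (image or str(n_record)),
                points=points,
                scale=scale,
            )
        )
        n_record += 1
    if not configs:
        warnings.warn(f"TPS file {path} contains no records", stacklevel=2)
    return configs


def write_tps(configs: list[LandmarkConfiguration], path: str | Path) -> None:
    """Write configurations in the TPS dialect (deterministic ordering).

    Coordinates are written exactly as stored (``repr`` precision) so a
    write/read round trip reproduces them bit-for-bit; SCALE is not re-emitted
    because stored coordinates already include it.
    """
    if configs:
        counts = {c.n_landmarks for c in configs}
        if len(counts) > 1:
            raise ValueError(f"heterogeneous landmark counts: {sorted(counts)}")
    path = Path(path)
    out = []
    for c in configs:
        out.append(f"LM={c.n_landmarks}")
        for x, y in c.points:
            out.append(f"{float(x)!r} {float(y)!r}")
        out.append(f"ID={c.specimen_id}")
    path.write_text("\n".join(out) + ("\n" if out else ""))


def read_scheme(path: str | Path) -> LandmarkScheme:
    roles, curves, indices = [], [], []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 3:
            raise SchemaError(f"bad scheme line {raw!r}")
        indices.append(int(parts[0]))
        roles.append(parts[1])
        curves.append(None if parts[2] == "-" else parts[2])
    if indices != list(range(len(indices))):
        raise SchemaError("scheme indices must be 0..k-1 in order")
    return LandmarkScheme(roles=np.array(roles, dtype=object),
                          curve_ids=np.array(curves, dtype=object))


def write_scheme(scheme: LandmarkScheme, path: str | Path) -> None:
    lines = ["# index role curve_id"]
    for i, (role, cid) in enumerate(zip(scheme.roles, scheme.curve_ids)):
        lines.append(f"{i} {role} {cid if cid is not None else '-'}")
    Path(path).write_text("\n".join(lines) + "\n")


def _read_table(path: str | Path) -> pd.DataFrame:
    # comma default, tab accepted
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [str(c).strip() for c in df.columns]
    return df


def read_specimen_table(path: str | Path) -> pd.DataFrame:
    """Read and validate the per-face covariate table.

    Requires ``id, sex, age, L, a, b, width1, width2, height1, height2`` plus
    either ``bmi`` or both ``weight`` and ``height``. Sex must be
    male/female.
    """
    df = _read_table(path)
    missing = [c for c in REQUIRED_SPECIMEN_COLUMNS if c not in df.columns]
    if "bmi" not in df.columns and not {"weight", "height"} <= set(df.columns):
        missing.append("bmi (or weight+height)")
    if missing:
        raise SchemaError(f"specimen table missing columns: {missing}")
    df = df.copy()
    df["id"] = df["id"].astype(str)
    df["sex"] = df["sex"].astype(str).str.strip().str.lower()
    bad_sex = set(df["sex"]) - {"male", "female"}
    if bad_sex:
        raise SchemaError(f"invalid sex values: {sorted(bad_sex)}")
    numeric = [c for c in df.columns if c not in ("id", "sex")]
    for c in numeric:
        df[c] = pd.to_numeric(df[c], errors="raise")
    return df


def write_specimen_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_ratings(path: str | Path):
    """Read a raters x stimuli rating matrix (first column = rater_id).

    Ratings must be integers in [1, 7] or missing. Returns a
    :class:`morphopath.measures.RatingMatrix`.
    """
    from .measures import RatingMatrix

    df = _read_table(path)
    if df.shape[1] < 2:
        raise SchemaError("rating matrix needs rater_id plus >= 1 stimulus column")
    first = df.columns[0]
    if first != "rater_id":
        raise SchemaError(f"first column must be 'rater_id', got {first!r}")
    df = df.set_index("rater_id")
    values = df.to_numpy(dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size and (np.any(finite < 1) or np.any(finite > 7)):
        raise SchemaError("ratings outside the 1-7 scale")
    if finite.size and np.any(finite != np.round(finite)):
        raise SchemaError("ratings must be integers")
    return RatingMatrix(
        values=values,
        rater_ids=[str(r) for r in df.index],
        stimulus_ids=[str(c) for c in df.columns],
    )
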