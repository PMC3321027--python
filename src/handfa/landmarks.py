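"""Landmark tables and the hand distance scheme.

Bilateral hand morphometrics are recorded as 2-D landmark coordinates per
(individual, side, digitization session).  This module defines the canonical
26-landmark hand scheme, reads landmark tables from CSV or TPS files, and
turns coordinates into the 21 Euclidean inter-landmark distances that the
asymmetry analysis consumes.

Distances are chirality-invariant, so left hands are never mirrored.
Coordinates are unit-agnostic (cm, mm or px); distances inherit the input
unit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MeasurementScheme",
    "default_hand_scheme",
    "read_landmark_table",
    "compute_distances",
    "LANDMARK_COLUMNS",
    "TRAIT_ORDER",
]

LANDMARK_COLUMNS = ["individual", "side", "session", "landmark", "x", "y"]

#: Trait labels in report order: palm width, total digit lengths, first/second/
#: third phalange lengths per digit, first-joint widths.
TRAIT_ORDER = (
    ["P"]
    + [f"D{d}" for d in (2, 3, 4, 5)]
    + [f"D{d}1" for d in (2, 3, 4, 5)]
    + [f"D{d}2" for d in (2, 3, 4, 5)]
    + [f"D{d}3" for d in (2, 3, 4, 5)]
    + [f"W{d}" for d in (2, 3, 4, 5)]
)


@dataclass(frozen=True)
class TraitDef:
    """One distance trait: an ordered landmark pair plus metadata."""

    pair: tuple[str, str]
    digit: int | None  # 2..5 for digit traits, None for the palm
    kind: str  # digit_length | phalange1 | phalange2 | phalange3 | joint_width | palm_width


@dataclass(frozen=True)
class MeasurementScheme:
    """Mapping from trait ids to landmark pairs.

    ``landmarks`` is the canonical landmark list; every pair must reference
    only canonical landmarks and trait ids must be unique (enforced on
    construction).
    """

    traits: dict[str, TraitDef]
    landmarks: tuple[str, ...] = field(default=())

    def __post_init__(self):
        lm = set(self.landmarks)
        for tid, tdef in self.traits.items():
            a, b = tdef.pair
            missing = {a, b} - lm
            if missing:
                raise ValueError(
                    f"trait {tid!r} references unknown landmarks: {sorted(missing)}"
                )

    @property
    def trait_ids(self) -> list[str]:
        return list(self.traits)

    def pair(self, trait_id: str) -> tuple[str, str]:
        return self.traits[trait_id].pair


def default_hand_scheme() -> MeasurementScheme:
    """The canonical 26-landmark, 21-distance hand scheme.

    Per digit D2-D5 (index to little finger): fingertip, base crease, the two
    inter-phalangeal crease points, and the two sides of the first
    (proximal inter-phalangeal) joint -- 24 landmarks; plus the tips of the
    distal and proximal palmar creases -- 26 in total.

    Traits per digit: total length (tip-base), the three phalange lengths
    along consecutive crease points, and the first-joint width; plus the palm
    width.  21 distances, labelled P, D2-D5, D21..D53, W2-W5.
    """
    landmarks: list[str] = []
    traits: dict[str, TraitDef] = {}

    landmarks += ["palm_distal", "palm_proximal"]
    traits["P"] = TraitDef(("palm_distal", "palm_proximal"), None, "palm_width")

    for d in (2, 3, 4, 5):
        tip, base = f"D{d}_tip", f"D{d}_base"
        c1, c2 = f"D{d}_crease1", f"D{d}_crease2"
        j1, j2 = f"D{d}_joint_a", f"D{d}_joint_b"
        landmarks += [tip, base, c1, c2, j1, j2]
        traits[f"D{d}"] = TraitDef((tip, base), d, "digit_length")
        traits[f"D{d}1"] = TraitDef((base, c1), d, "phalange1")
        traits[f"D{d}2"] = TraitDef((c1, c2), d, "phalange2")
        traits[f"D{d}3"] = TraitDef((c2, tip), d, "phalange3")
        traits[f"W{d}"] = TraitDef((j1, j2), d, "joint_width")

    # report order
    ordered = {tid: traits[tid] for tid in TRAIT_ORDER}
    return MeasurementScheme(traits=ordered, landmarks=tuple(landmarks))


def _validate_landmark_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in LANDMARK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"landmark table missing columns: {missing}")
    df = df[LANDMARK_COLUMNS].copy()
    for c in ("x", "y"):
        df[c] = pd.to_numeric(df[c], errors="raise")
    if not np.isfinite(df[["x", "y"]].to_numpy()).all():
        raise ValueError("non-finite coordinates in landmark table")
    bad_side = set(df["side"].unique()) - {"L", "R"}
    if bad_side:
        raise ValueError(f"side must be 'L' or 'R', got {sorted(bad_side)}")
    key = ["individual", "side", "session", "landmark"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        offender = df.loc[dup, key].iloc[0].tolist()
        raise ValueError(
            f"duplicate landmark record for (individual, side, session, landmark) = {offender}"
        )
    return df


_TPS_LM = re.compile(r"^\s*LM\s*=\s*(\d+)\s*$", re.IGNORECASE)
_TPS_KV = re.compile(r"^\s*([A-Z]+)\s*=\s*(.*?)\s*$")


def _read_tps(path: str, landmark_names: list[str] | None) -> pd.DataFrame:
    """Parse a TPS file into long format.

    Dialect: each specimen block is ``LM=<n>`` followed by n ``x y`` lines and
    an ``ID=<individual>_<L|R>_<session>`` line (SCALE/IMAGE lines are
    ignored).  Landmarks are named positionally from ``landmark_names`` or
    ``lm01``..``lmNN``.
    """
    rows = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        line = lines[i]
        if not line.strip():
            i += 1
            continue
        m = _TPS_LM.match(line)
        if not m:
            raise ValueError(f"TPS parse error at line {i + 1}: expected LM=, got {line!r}")
        n_lm = int(m.group(1))
        coords = []
        i += 1
        for _ in range(n_lm):
            parts = lines[i].split()
            if len(parts) != 2:
                raise ValueError(f"TPS parse error at line {i + 1}: expected 'x y'")
            coords.append((float(parts[0]), float(parts[1])))
            i += 1
        spec_id = None
        while i < len(lines) and lines[i].strip() and not _TPS_LM.match(lines[i]):
            kv = _TPS_KV.match(lines[i])
            if kv and kv.group(1).upper() == "ID":
                spec_id = kv.group(2)
            i += 1
        if spec_id is None:
            raise ValueError("TPS block without ID= line")
        try:
            individual, side, session = spec_id.rsplit("_", 2)
        except ValueError:
            raise ValueError(
                f"TPS ID {spec_id!r} not of the form <individual>_<L|R>_<session>"
            ) from None
        names = landmark_names or [f"lm{k + 1:02d}" for k in range(n_lm)]
        if len(names) != n_lm:
            raise ValueError(
                f"TPS block has {n_lm} landmarks but {len(names)} names were supplied"
            )
        for name, (x, y) in zip(names, coords):
            rows.append((individual, side, int(session), name, x, y))
    return pd.DataFrame(rows, columns=LANDMARK_COLUMNS)


def read_landmark_table(
    path: str,
    format: str = "csv",
    landmark_names: list[str] | None = None,
) -> pd.DataFrame:
    """Read and validate a landmark coordinate table.

    Parameters
    ----------
    path
        File path.
    format
        ``"csv"`` (columns individual,side,session,landmark,x,y) or ``"tps"``.
    landmark_names
        For TPS input: canonical names assigned to the numbered points, in
        file order (e.g. ``default_hand_scheme().landmarks``).
    """
    if format == "csv":
        df = pd.read_csv(path)
    elif format == "tps":
        df = _read_tps(path, landmark_names)
    else:
        raise ValueError(f"unknown landmark format {format!r}")
    return _validate_landmark_table(df)


def compute_distances(
    landmarks: pd.DataFrame, scheme: MeasurementScheme
) -> pd.DataFrame:
    """Euclidean inter-landmark distances per (individual, side, session).

    Returns the long measurement table with columns
    ``individual, side, session, trait, value``.  Every landmark referenced by
    the scheme must be present in every group; missing landmarks raise with
    the absentees listed rather than being skipped.
    """
    landmarks = _validate_landmark_table(landmarks)
    needed = sorted({lm for td in scheme.traits.values() for lm in td.pair})
    wide = landmarks.pivot_table(
        index=["individual", "side", "session"],
        columns="landmark",
        values=["x", "y"],
        aggfunc="first",
        sort=True,
    )
    absent_msgs = []
    for lm in needed:
        if ("x", lm) not in wide.columns:
            absent_msgs.append(f"{lm} (all groups)")
    if not absent_msgs:
        sub = wide.loc[:, [("x", lm) for lm in needed] + [("y", lm) for lm in needed]]
        nan_rows = sub.isna().any(axis=1)
        for idx in wide.index[nan_rows]:
            miss = [lm for lm in needed if pd.isna(wide.loc[idx, ("x", lm)])]
            absent_msgs.append(f"group {idx}: missing {miss}")
    if absent_msgs:
        raise ValueError("landmarks required by scheme are absent: " + "; ".join(absent_msgs))

    out = {}
    for tid, tdef in scheme.traits.items():
        a, b = tdef.pair
        dx = wide[("x", a)] - wide[("x", b)]
        dy = wide[("y", a)] - wide[("y", b)]
        out[tid] = np.hypot(dx, dy)
    res = pd.DataFrame(out)
    res = res.stack().rename("value").reset_index()
    res = res.rename(columns={"landmark": "trait", "level_3": "trait"})
    res.columns = ["individual", "side", "session", "trait", "value"]
    # preserve scheme trait order within groups
    res["trait"] = pd.Categorical(res["trait"], categories=list(scheme.traits), ordered=True)
    res = res.sort_values(["individual", "side", "session", "trait"]).reset_index(drop=True)
    res["trait"] = res["trait"].astype(str)
    return res
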