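"""Frame-stack and annotation I/O plus deterministic dataset splitting.

HDF5 layout for frame stacks::

    /frames      (N, H, W)  int32 (or float64 for processed stacks)
    /mask        (H, W)     uint8, optional; absent means all-trusted
    /frame_ids   (N,)       variable-length strings
    attrs: beam_center_row, beam_center_col, source_tag

Annotations are CSV files with header ``frame_id,label,spot_count,source``;
``spot_count`` may be empty.  Splitting and subsampling use a single seeded
NumPy ``default_rng`` (PCG64) permutation followed by contiguous slicing so
results are reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Label",
    "FormatError",
    "DetectorFrame",
    "FrameStack",
    "AnnotationTable",
    "SplitSpec",
    "read_frame_stack",
    "write_frame_stack",
    "read_annotations",
    "write_annotations",
    "split_dataset",
    "subsample_training",
]

#: generator used for all seeded permutations; recorded in config echoes
RNG_ALGORITHM = "numpy.random.PCG64"

VALID_SOURCES = ("expert", "rule", "spotfinder")


class FormatError(ValueError):
    """A file does not follow the expected on-disk layout."""


class Label(IntEnum):
    """Per-frame class.  Integer codes fix the classification-vector order."""

    HIT = 0
    MAYBE = 1
    MISS = 2

    @classmethod
    def parse(cls, text: str) -> "Label":
        try:
            return cls[str(text).strip().upper()]
        except KeyError:
            raise FormatError(f"unknown label {text!r}") from None

    def __str__(self) -> str:  # CSV serialization: 'Hit', 'Maybe', 'Miss'
        return self.name.capitalize()


@dataclass
class DetectorFrame:
    """One 2D detector exposure.

    ``pixels`` and ``mask`` share a shape; untrusted pixels are forced to 0
    on construction.  ``beam_center`` is (row, col) in pixel units and must
    lie inside the grid.
    """

    pixels: np.ndarray
    mask: np.ndarray
    beam_center: tuple[float, float]
    frame_id: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be 2D")
        if self.pixels.shape != self.mask.shape:
            raise ValueError(
                f"pixels shape {self.pixels.shape} != mask shape {self.mask.shape}"
            )
        r, c = self.beam_center
        h, w = self.pixels.shape
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"beam_center {self.beam_center} outside {h}x{w} grid")
        if not self.mask.all():
            self.pixels = np.where(self.mask, self.pixels, 0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class FrameStack:
    """Ordered collection of frames sharing one shape."""

    frames: list[DetectorFrame]
    source_tag: str = ""

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("FrameStack must contain at least one frame")
        shape = self.frames[0].shape
        for f in self.frames:
            if f.shape != shape:
                raise ValueError("all frames in a stack must share one shape")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i: int) -> DetectorFrame:
        return self.frames[i]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    def pixel_array(self) -> np.ndarray:
        """(N, H, W) array of all pixel grids."""
        return np.stack([f.pixels for f in self.frames])


@dataclass
class AnnotationTable:
    """Per-frame ground truth: label, optional spot count and provenance."""

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = ["frame_id", "label", "spot_count", "source"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"annotation table missing columns {missing}")
        if self.df["frame_id"].duplicated().any():
            dupes = self.df.loc[self.df["frame_id"].duplicated(), "frame_id"]
            raise ValueError(f"duplicate frame_id(s): {sorted(set(dupes))[:5]}")
        bad = set(self.df["source"]) - set(VALID_SOURCES)
        if bad:
            raise ValueError(f"unknown annotation source(s): {sorted(bad)}")
        self.df = self.df.reset_index(drop=True)

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, Label, int | None, str]],
    ) -> "AnnotationTable":
        rows = list(records)
        df = pd.DataFrame(rows, columns=["frame_id", "label", "spot_count", "source"])
        df["label"] = [Label(l) for l in df["label"]]
        df["spot_count"] = df["spot_count"].astype("Int64")
        return cls(df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def frame_ids(self) -> list[str]:
        return list(self.df["frame_id"])

    @property
    def labels(self) -> np.ndarray:
        return np.array([int(l) for l in self.df["label"]])

    def label_of(self, frame_id: str) -> Label:
        row = self.df.loc[self.df["frame_id"] == frame_id]
        if row.empty:
            raise KeyError(frame_id)
        return Label(row["label"].iloc[0])

    def class_counts(self) -> dict[Label, int]:
        out = {lab: 0 for lab in Label}
        for l in self.df["label"]:
            out[Label(l)] += 1
        return out

    def select(self, frame_ids: Sequence[str]) -> "AnnotationTable":
        wanted = set(frame_ids)
        sub = self.df[self.df["frame_id"].isin(wanted)].copy()
        return AnnotationTable(sub)


@dataclass
class SplitSpec:
    """Train/validation/test fractions, split seed and stratification flag."""

    fractions: tuple[float, float, float] = (0.5, 0.2, 0.3)
    seed: int = 0
    ratio_preserving: bool = False

    def __post_init__(self) -> None:
        fr = self.fractions
        if len(fr) != 3 or any(f < 0 or f > 1 for f in fr):
            raise ValueError("fractions must be three values in [0, 1]")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {sum(fr)}")


# ---------------------------------------------------------------------------
# HDF5 frame stacks


def write_frame_stack(stack: FrameStack, path) -> None:
    """Write *stack* to HDF5.

    Integer pixel data are stored as 4-byte signed integers; floating-point
    data (e.g. normalized stacks) as float64 so round-trips are bit-exact
    either way.  A single /mask dataset is stored (shared by all frames)
    unless every frame is fully trusted.
    """
    pixels = stack.pixel_array()
    if np.issubdtype(pixels.dtype, np.integer) or np.all(pixels == np.round(pixels)):
        data = pixels.astype(np.int32)
    else:
        data = pixels.astype(np.float64)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("frames", data=data)
        mask = stack.frames[0].mask
        if not all(np.array_equal(f.mask, mask) for f in stack.frames):
            raise ValueError("all frames in a stored stack must share one mask")
        if not mask.all():
            h5.create_dataset("mask", data=mask.astype(np.uint8))
        ids = [f.frame_id for f in stack.frames]
        h5.create_dataset("frame_ids", data=np.array(ids, dtype=object),
                          dtype=h5py.string_dtype())
        r, c = stack.frames[0].beam_center
        h5.attrs["beam_center_row"] = float(r)
        h5.attrs["beam_center_col"] = float(c)
        h5.attrs["source_tag"] = stack.source_tag


def read_frame_stack(path) -> FrameStack:
    """Read a frame stack written by :func:`write_frame_stack`."""
    with h5py.File(path, "r") as h5:
        if "frames" not in h5:
            raise FormatError(f"{path}: missing /frames dataset")
        frames = h5["frames"][...]
        if frames.ndim != 3:
            raise FormatError(f"{path}: /frames must be (N, H, W)")
        n, h, w = frames.shape
        if "mask" in h5:
            mask = h5["mask"][...].astype(bool)
            if mask.shape != (h, w):
                raise FormatError(
                    f"{path}: mask shape {mask.shape} != frame shape {(h, w)}"
                )
        else:
            mask = np.ones((h, w), dtype=bool)
        if "frame_ids" in h5:
            ids = [s.decode() if isinstance(s, bytes) else str(s)
                   for s in h5["frame_ids"][...]]
        else:
            ids = [f"f{i:05d}" for i in range(n)]
        bc = (
            float(h5.attrs.get("beam_center_row", (h - 1) / 2)),
            float(h5.attrs.get("beam_center_col", (w - 1) / 2)),
        )
        tag = str(h5.attrs.get("source_tag", ""))
    out = [
        DetectorFrame(pixels=frames[i], mask=mask, beam_center=bc, frame_id=ids[i])
        for i in range(n)
    ]
    return FrameStack(out, source_tag=tag)


# ---------------------------------------------------------------------------
# CSV annotations


def write_annotations(table: AnnotationTable, path) -> None:
    df = table.df.copy()
    df["label"] = [str(Label(l)) for l in df["label"]]
    df.to_csv(path, index=False)


def read_annotations(path) -> AnnotationTable:
    df = pd.read_csv(path, dtype={"frame_id": str, "source": str})
    required = ["frame_id", "label", "spot_count", "source"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df["label"] = [Label.parse(l) for l in df["label"]]
    df["spot_count"] = df["spot_count"].astype("Int64")
    return AnnotationTable(df)


# ---------------------------------------------------------------------------
# Splitting and subsampling


def _slice_boundaries(n: int, fractions: Sequence[float]) -> list[int]:
    # cumulative rounding keeps every part within 1 of n * fraction
    cum = np.cumsum(fractions)
    return [int(round(c * n)) for c in cum]


def _split_ids(ids: list[str], fractions, rng) -> list[list[str]]:
    perm = rng.permutation(len(ids))
    shuffled = [ids[i] for i in perm]
    b = _slice_boundaries(len(ids), fractions)
    return [shuffled[: b[0]], shuffled[b[0]: b[1]], shuffled[b[1]: b[2]]]


def split_dataset(
    table: AnnotationTable, spec: SplitSpec
) -> tuple[AnnotationTable, AnnotationTable, AnnotationTable]:
    """Partition *table* into train/validation/test.

    The partition is disjoint and exhaustive, deterministic given
    ``spec.seed``.  With ``ratio_preserving`` the permutation-and-slice is
    applied per class, so each part matches the whole table's class mix
    within one frame per class.
    """
    if len(table) == 0:
        raise ValueError("cannot split an empty table")
    rng = np.random.default_rng(spec.seed)
    if spec.ratio_preserving:
        parts: list[list[str]] = [[], [], []]
        for lab in Label:
            ids = [
                fid
                for fid, l in zip(table.df["frame_id"], table.df["label"])
                if Label(l) == lab
            ]
            if not ids:
                continue
            for part, chunk in zip(parts, _split_ids(ids, spec.fractions, rng)):
                part.extend(chunk)
    else:
        parts = _split_ids(table.frame_ids, spec.fractions, rng)
    return tuple(table.select(p) for p in parts)  # type: ignore[return-value]


def subsample_training(table: AnnotationTable, n: int, seed: int) -> AnnotationTable:
    """Random sub-selection of *n* rows preserving the class ratio within 1."""
    if n > len(table):
        raise ValueError(f"cannot subsample {n} rows from {len(table)}")
    rng = np.random.default_rng(seed)
    counts = table.class_counts()
    total = len(table)
    # largest-remainder apportionment of n across the classes present
    present = [lab for lab in Label if counts[lab] > 0]
    quotas = {lab: n * counts[lab] / total for lab in present}
    take = {lab: int(np.floor(quotas[lab])) for lab in present}
    rest = n - sum(take.values())
    for lab in sorted(present, key=lambda l: quotas[l] - take[l], reverse=True)[:rest]:
        take[lab] += 1
    chosen: list[str] = []
    for lab in present:
        ids = [
            fid
            for fid, l in zip(table.df["frame_id"], table.df["label"])
            if Label(l) == lab
        ]
        pick = rng.permutation(len(ids))[: take[lab]]
        chosen.extend(ids[i] for i in pick)
    return table.select(chosen)
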