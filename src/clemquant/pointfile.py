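"""Coordinate-file I/O in a model2point-style whitespace dialect.

Each data line is ``object contour x y z`` (whitespace separated).
Object id 1 holds membrane contours, object id 2 particle markers; the
``z`` column is the serial-section / image index, so one file can hold
several micrographs.  Lines starting with ``#`` are comments.  Coordinates
are stored in pixels and scaled to nm on read using the per-image metadata
(a flat ``key = value`` file).

Metadata keys::

    nm_per_px = 2.0
    width_px = 1024
    height_px = 768
    section_thickness_nm = 70
    condition = rapamycin
    experiment_id = expt1
    side_convention = left
    contour<k>.coat = s0:s1, s0:s1       # nm arc positions, k is 1-based
    contour<k>.pit = s0:s1
    image<z>.contour<k>.coat = s0:s1     # override for one image index
    image<z>.contour<k>.pit = s0:s1

Unscoped contour keys apply to the k-th contour of every image in the
file; ``image<z>.``-scoped keys override them for that image.
"""

from __future__ import annotations

import io
from typing import Iterable, TextIO

import numpy as np

from .annotations import ImageFrame, MembraneContour, MicrographAnnotation, Particle

__all__ = [
    "read_point_file",
    "write_point_file",
    "read_metadata",
    "write_metadata",
    "annotations_from_streams",
]

OBJECT_MEMBRANE = 1
OBJECT_PARTICLE = 2
_ADMISSIBLE = (OBJECT_MEMBRANE, OBJECT_PARTICLE)


class PointFileError(ValueError):
    pass


def _parse_lines(stream: TextIO):
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 5:
            raise PointFileError(
                f"line {lineno}: expected >= 5 whitespace-separated fields, got {len(fields)}"
            )
        try:
            obj = int(float(fields[0]))
            cont = int(float(fields[1]))
            x, y, z = (float(f) for f in fields[2:5])
        except ValueError as e:
            raise PointFileError(f"line {lineno}: non-numeric field ({e})") from e
        if obj not in _ADMISSIBLE:
            raise PointFileError(
                f"line {lineno}: unknown object id {obj}; admissible ids are "
                f"{OBJECT_MEMBRANE} (membrane contour) and {OBJECT_PARTICLE} (particle)"
            )
        yield obj, cont, x, y, int(round(z))


def read_point_file(
    stream: TextIO | str,
    frame: ImageFrame,
    condition: str = "",
    experiment_id: str = "",
    side_convention: str = "left",
    coat_intervals_nm: dict[int, list[tuple[float, float]]] | None = None,
    pit_marks_nm: dict[int, tuple[float, float]] | None = None,
    per_image: dict[int, dict] | None = None,
) -> list[MicrographAnnotation]:
    """Parse a point file into one annotation per distinct z (image index).

    Contours are grouped by ``(object, contour)`` id in file order;
    coordinates are converted px -> nm.  ``coat_intervals_nm`` /
    ``pit_marks_nm`` are keyed by 1-based contour order within each image;
    ``per_image`` maps an image index to overriding
    ``{"coat_intervals_nm": ..., "pit_marks_nm": ...}`` dicts.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    by_image: dict[int, dict] = {}
    for obj, cont, x, y, z in _parse_lines(stream):
        img = by_image.setdefault(z, {"contours": {}, "particles": []})
        if obj == OBJECT_MEMBRANE:
            img["contours"].setdefault(cont, []).append((x, y))
        else:
            img["particles"].append((x, y))

    s = frame.nm_per_px
    out = []
    for z in sorted(by_image):
        img = by_image[z]
        override = (per_image or {}).get(z, {})
        coat_map = override.get("coat_intervals_nm", coat_intervals_nm or {})
        pit_map = override.get("pit_marks_nm", pit_marks_nm or {})
        contours = []
        for k, (_, verts) in enumerate(sorted(img["contours"].items()), start=1):
            coat = coat_map.get(k, [])
            pit = pit_map.get(k)
            contours.append(
                MembraneContour(
                    np.asarray(verts, dtype=float) * s,
                    coat_intervals=coat,
                    pit_marks=pit,
                    side_convention=side_convention,
                )
            )
        particles = [Particle((x * s, y * s)) for x, y in img["particles"]]
        out.append(
            MicrographAnnotation(
                frame=frame,
                contours=contours,
                particles=particles,
                condition=condition,
                experiment_id=experiment_id,
                image_index=z,
            )
        )
    return out


def write_point_file(annotations: Iterable[MicrographAnnotation], stream: TextIO) -> None:
    """Write annotations back to the point dialect (nm -> px, full precision)."""
    stream.write("# object contour x y z\n")
    for ann in annotations:
        s = ann.frame.nm_per_px
        z = ann.image_index
        for ci, c in enumerate(ann.contours, start=1):
            for x, y in c.vertices:
                stream.write(f"{OBJECT_MEMBRANE} {ci} {x / s:.6f} {y / s:.6f} {z}\n")
        for p in ann.particles:
            x, y = p.center
            stream.write(f"{OBJECT_PARTICLE} 1 {x / s:.6f} {y / s:.6f} {z}\n")


# ---------------------------------------------------------------------------
# flat key-value metadata


def _parse_interval_list(text: str) -> list[tuple[float, float]]:
    out = []
    for part in text.split(","):
        part = part.strip()
        if not part:
            continue
        a, b = part.split(":")
        out.append((float(a), float(b)))
    return out


def read_metadata(stream: TextIO | str) -> dict:
    """Read a flat ``key = value`` metadata file into a dict.

    Contour-level keys are collected into ``coat_intervals_nm`` and
    ``pit_marks_nm`` dicts keyed by 1-based contour index.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    raw: dict[str, str] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise PointFileError(f"metadata line {lineno}: expected 'key = value'")
        k, v = line.split("=", 1)
        raw[k.strip()] = v.strip()

    meta: dict = {
        "nm_per_px": float(raw.get("nm_per_px", 1.0)),
        "width_px": int(raw["width_px"]),
        "height_px": int(raw["height_px"]),
        "section_thickness_nm": float(raw.get("section_thickness_nm", 70.0)),
        "condition": raw.get("condition", ""),
        "experiment_id": raw.get("experiment_id", ""),
        "side_convention": raw.get("side_convention", "left"),
        "coat_intervals_nm": {},
        "pit_marks_nm": {},
        "per_image": {},
    }

    def _contour_key(key: str, suffix: str) -> int:
        return int(key[len("contour"):-len(suffix)])

    for k, v in raw.items():
        scope = meta
        if k.startswith("image"):
            z_txt, _, k = k.partition(".")
            z = int(z_txt[len("image"):])
            scope = meta["per_image"].setdefault(
                z, {"coat_intervals_nm": {}, "pit_marks_nm": {}})
        if k.startswith("contour") and k.endswith(".coat"):
            scope["coat_intervals_nm"][_contour_key(k, ".coat")] = \
                _parse_interval_list(v)
        elif k.startswith("contour") and k.endswith(".pit"):
            (interval,) = _parse_interval_list(v)
            scope["pit_marks_nm"][_contour_key(k, ".pit")] = interval
    return meta


def write_metadata(meta: dict, stream: TextIO) -> None:
    for key in ("nm_per_px", "width_px", "height_px", "section_thickness_nm",
                "condition", "experiment_id", "side_convention"):
        if key in meta and meta[key] != "":
            stream.write(f"{key} = {meta[key]}\n")
    def _write_marks(prefix: str, scope: dict) -> None:
        for idx, ivals in scope.get("coat_intervals_nm", {}).items():
            txt = ", ".join(f"{a:.6f}:{b:.6f}" for a, b in ivals)
            stream.write(f"{prefix}contour{idx}.coat = {txt}\n")
        for idx, (a, b) in scope.get("pit_marks_nm", {}).items():
            stream.write(f"{prefix}contour{idx}.pit = {a:.6f}:{b:.6f}\n")

    _write_marks("", meta)
    for z, scope in meta.get("per_image", {}).items():
        _write_marks(f"image{z}.", scope)


def annotations_from_streams(points: TextIO | str, metadata: TextIO | str) -> list[MicrographAnnotation]:
    """Convenience: metadata + point file -> annotations."""
    meta = read_metadata(metadata)
    frame = ImageFrame(
        width_px=meta["width_px"],
        height_px=meta["height_px"],
        nm_per_px=meta["nm_per_px"],
        section_thickness_nm=meta["section_thickness_nm"],
    )
    return read_point_file(
        points,
        frame,
        condition=meta["condition"],
        experiment_id=meta["experiment_id"],
        side_convention=meta["side_convention"],
        coat_intervals_nm=meta["coat_intervals_nm"],
        pit_marks_nm=meta["pit_marks_nm"],
        per_image=meta.get("per_image"),
    )
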