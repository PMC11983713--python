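"""XYZ / extended-XYZ files, flat key-value configs, and TSV tables.

The extended-XYZ dialect is the de-facto one: an optional
``Lattice="ax ay az bx by bz cx cy cz"`` entry (orthorhombic only) and a
``Properties=species:S:1:pos:R:3[:charge:R:1][:vel:R:3]`` column declaration
in the comment line.  Molecule topology is inferred on load from O–H
distances < 1.3 Å.
"""

from __future__ import annotations

import ast
import re
from pathlib import Path

import numpy as np

from .system import Configuration

__all__ = ["read_xyz", "write_xyz", "read_xyz_frames", "write_xyz_frames",
           "parse_config_file", "write_config_file", "write_tsv", "XYZParseError"]


class XYZParseError(ValueError):
    """Malformed XYZ input, reported with the offending line number."""


def _parse_comment(comment: str):
    cell = None
    fields = [("species", 1), ("pos", 3)]
    m = re.search(r'Lattice="([^"]+)"', comment)
    if m:
        lat = np.fromstring(m.group(1), sep=" ")
        if lat.size != 9:
            raise XYZParseError("Lattice must hold nine floats")
        lat = lat.reshape(3, 3)
        if np.abs(lat - np.diag(np.diag(lat))).max() > 1e-10:
            raise XYZParseError("only orthorhombic (diagonal) lattices are supported")
        cell = np.diag(lat).copy()
    m = re.search(r"Properties=(\S+)", comment)
    if m:
        toks = m.group(1).split(":")
        fields = [(toks[i], int(toks[i + 2])) for i in range(0, len(toks), 3)]
    return cell, fields


def _parse_frame(lines, lineno0: int):
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise XYZParseError(f"line {lineno0 + 1}: expected an atom count")
    if len(lines) < n + 2:
        raise XYZParseError(f"line {lineno0 + 1}: truncated frame ({n} atoms declared)")
    cell, fields = _parse_comment(lines[1])
    species, rows = [], []
    for k in range(n):
        ln = lines[2 + k].split()
        width = sum(w for _, w in fields)
        if len(ln) < width:
            raise XYZParseError(
                f"line {lineno0 + 3 + k}: expected {width} columns, got {len(ln)}")
        rows.append(ln)
    data = {}
    col = 0
    for name, width in fields:
        if name == "species":
            species = [r[col] for r in rows]
        else:
            try:
                data[name] = np.array(
                    [[float(v) for v in r[col:col + width]] for r in rows])
            except ValueError as err:
                raise XYZParseError(f"frame at line {lineno0 + 1}: {err}")
        col += width
    # topology is always inferred on load (O–H distance < 1.3 Å)
    from .system import infer_topology
    species = np.asarray(species, dtype=object)
    order = infer_topology(species, data["pos"], cell)
    config = Configuration(
        species[order], data["pos"][order],
        velocities=data["vel"][order] if "vel" in data else None, cell=cell,
        charges=data["charge"][order, 0] if "charge" in data else None)
    return config, n + 2


def read_xyz_frames(path) -> list[Configuration]:
    lines = Path(path).read_text().splitlines()
    frames = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        config, used = _parse_frame(lines[i:], i)
        frames.append(config)
        i += used
    if not frames:
        raise XYZParseError(f"{path}: no frames found")
    return frames


def read_xyz(path) -> Configuration:
    """First (usually only) frame of an (extended-)XYZ file."""
    return read_xyz_frames(path)[0]


def _format_frame(config: Configuration, comment: str | None = None) -> str:
    fields = ["species:S:1", "pos:R:3"]
    if config.charges is not None:
        fields.append("charge:R:1")
    if config.velocities is not None:
        fields.append("vel:R:3")
    parts = []
    if config.cell is not None:
        l = config.cell
        parts.append(
            f'Lattice="{l[0]:.10f} 0.0 0.0 0.0 {l[1]:.10f} 0.0 0.0 0.0 {l[2]:.10f}"')
    parts.append("Properties=" + ":".join(fields))
    if comment:
        parts.append(comment)
    out = [str(config.n_atoms), " ".join(parts)]
    for i in range(config.n_atoms):
        row = [f"{config.species[i]:2s}"]
        row += [f"{v:18.10f}" for v in config.positions[i]]
        if config.charges is not None:
            row.append(f"{config.charges[i]:14.10f}")
        if config.velocities is not None:
            row += [f"{v:16.10f}" for v in config.velocities[i]]
        out.append(" ".join(row))
    return "\n".join(out) + "\n"


def write_xyz(path, config: Configuration, comment: str | None = None) -> None:
    Path(path).write_text(_format_frame(config, comment))


def write_xyz_frames(path, frames, comments=None) -> None:
    """Multi-frame extended XYZ (per-atom charges included when present)."""
    comments = comments or [None] * len(frames)
    Path(path).write_text(
        "".join(_format_frame(f, c) for f, c in zip(frames, comments)))


# ---------------------------------------------------------------------------
# flat key-value run configuration
# ---------------------------------------------------------------------------

def parse_config_file(path) -> dict:
    """``key = value`` lines; '#' comments; values parsed as python literals
    where possible, else kept as strings."""
    out = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (s.strip() for s in line.split("=", 1))
        try:
            out[key] = ast.literal_eval(value)
        except (ValueError, SyntaxError):
            out[key] = value
    return out


def write_config_file(path, config: dict) -> None:
    lines = [f"{k} = {v!r}" if isinstance(v, str) else f"{k} = {v}"
             for k, v in config.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def write_tsv(path, columns: dict, float_fmt: str = "{:.8g}") -> None:
    """Line-oriented TSV with a header naming every column (units included
    in the caller-chosen names)."""
    keys = list(columns)
    n = len(next(iter(columns.values())))
    rows = ["\t".join(keys)]
    for i in range(n):
        rows.append("\t".join(
            float_fmt.format(columns[k][i])
            if isinstance(columns[k][i], (float, np.floating))
            else str(columns[k][i]) for k in keys))
    Path(path).write_text("\n".join(rows) + "\n")
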