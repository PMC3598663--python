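"""Profile CSV reading and writing.

Format: UTF-8 comma-separated with ``#``-prefixed metadata lines, a
``congener,value`` header, then one row per congener (or homolog class,
for homolog-level tables).  Metadata:

* ``#unit: mol_percent|weight_percent`` (required)
* ``#total_uM: <float>`` (optional total PCB concentration)
* ``#label: <text>`` (optional)
* ``#seed: <int>`` (optional provenance for generated data)

The writer emits congeners in descending value order; a written profile
reads back identical up to float formatting.
"""

from __future__ import annotations

from pathlib import Path

from .congeners import CongenerError, parse_congener
from .profiles import CongenerProfile, ProfileError


class ProfileIOError(ProfileError):
    """Malformed profile file; messages carry line numbers."""


def _is_homolog_key(key: str) -> bool:
    from .profiles import _normalize_homolog_key

    return _normalize_homolog_key(key) is not None


def read_profile(path: str | Path) -> CongenerProfile:
    """Read a profile CSV, validating names, units, and duplicates."""
    path = Path(path)
    unit: str | None = None
    total_um: float | None = None
    label = ""
    rows: dict[str, tuple[float, int]] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                key = key.strip().lower()
                value = value.strip()
                if key == "unit":
                    unit = value
                elif key == "total_um":
                    total_um = float(value)
                elif key == "label":
                    label = value
            continue
        parts = [p.strip() for p in line.split(",")]
        if parts[0].lower() == "congener":
            continue  # header
        if len(parts) != 2:
            raise ProfileIOError(
                f"{path}:{lineno}: expected 'congener,value', got {line!r}"
            )
        name, value_str = parts
        if not _is_homolog_key(name):
            try:
                name = parse_congener(name).name
            except CongenerError as exc:
                raise ProfileIOError(f"{path}:{lineno}: {exc}") from exc
        try:
            value = float(value_str)
        except ValueError as exc:
            raise ProfileIOError(
                f"{path}:{lineno}: non-numeric value {value_str!r}"
            ) from exc
        if name in rows:
            first = rows[name][1]
            raise ProfileIOError(
                f"{path}:{lineno}: duplicate entry for {name!r} "
                f"(first seen at line {first})"
            )
        rows[name] = (value, lineno)
    if unit is None:
        raise ProfileIOError(f"{path}: missing '#unit:' metadata line")
    if unit not in ("mol_percent", "weight_percent"):
        raise ProfileIOError(f"{path}: unknown unit {unit!r}")
    if not rows:
        raise ProfileIOError(f"{path}: no data rows")
    try:
        return CongenerProfile(
            entries={k: v for k, (v, _) in rows.items()},
            unit=unit,
            total_um=total_um,
            label=label,
        )
    except ProfileError as exc:
        raise ProfileIOError(f"{path}: {exc}") from exc


def write_profile(
    p: CongenerProfile, path: str | Path, seed: int | None = None
) -> None:
    """Write a profile CSV (descending value order, lossless floats)."""
    lines = [f"#unit: {p.unit}"]
    if p.total_um is not None:
        lines.append(f"#total_uM: {p.total_um:g}")
    if p.label:
        lines.append(f"#label: {p.label}")
    if seed is not None:
        lines.append(f"#seed: {seed}")
    lines.append("congener,value")
    for name, value in sorted(p.entries.items(), key=lambda kv: (-kv[1], kv[0])):
        lines.append(f"{name},{value!r}")
    Path(path).write_text("\n".join(lines) + "\n")
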