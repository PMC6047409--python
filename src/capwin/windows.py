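"""Genomic windows for targeted-capture count analysis.

Windows are the fixed genomic intervals (typically capture-bait targets) in
which reads are counted. Coordinates are stored 0-based half-open throughout;
BED input is taken as-is and GFF3 input is converted on read (start-1) and
converted back on write.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from .errors import ParseError, ValidationError


class TargetClass(str, enum.Enum):
    """Classification of a window with respect to the capture design."""

    ON_TARGET = "on_target"
    OFF_TARGET = "off_target"
    CONTROL = "control"


@dataclass(frozen=True)
class GenomicWindow:
    """A genomic interval, 0-based half-open, with a target-class label."""

    chrom: str
    start: int
    end: int
    window_id: str
    target_class: TargetClass = TargetClass.ON_TARGET

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValidationError(
                f"window {self.window_id!r}: invalid interval "
                f"[{self.start}, {self.end}) on {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class WindowSet:
    """An ordered collection of windows with unique ids."""

    def __init__(self, windows: Iterable[GenomicWindow]):
        self._windows: list[GenomicWindow] = list(windows)
        seen: set[str] = set()
        for w in self._windows:
            if w.window_id in seen:
                raise ValidationError(f"duplicate window_id {w.window_id!r}")
            seen.add(w.window_id)

    def __len__(self) -> int:
        return len(self._windows)

    def __iter__(self) -> Iterator[GenomicWindow]:
        return iter(self._windows)

    def __getitem__(self, i: int) -> GenomicWindow:
        return self._windows[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WindowSet):
            return NotImplemented
        return self._windows == other._windows

    @property
    def ids(self) -> list[str]:
        return [w.window_id for w in self._windows]

    @property
    def chroms(self) -> list[str]:
        return sorted({w.chrom for w in self._windows})

    def by_class(self, target_class: TargetClass) -> "WindowSet":
        return WindowSet(w for w in self._windows if w.target_class == target_class)

    def with_controls(
        self, controls: "WindowSet | Sequence[str]"
    ) -> "WindowSet":
        """Return a copy with matching windows relabelled ``control``.

        Matching is by window_id first; windows given as intervals fall back
        to exact (chrom, start, end) match.
        """
        if isinstance(controls, WindowSet):
            ids = set(controls.ids)
            intervals = {(w.chrom, w.start, w.end) for w in controls}
        else:
            ids = set(controls)
            intervals = set()
        matched: set[str] = set()
        out = []
        for w in self._windows:
            if w.window_id in ids or (w.chrom, w.start, w.end) in intervals:
                matched.add(w.window_id)
                out.append(replace(w, target_class=TargetClass.CONTROL))
            else:
                out.append(w)
        if not matched:
            wanted = sorted(ids) or sorted(map(str, intervals))
            raise ValidationError(
                f"no control windows matched the experiment: {wanted}"
            )
        return WindowSet(out)


def _parse_target_class(
    name: str | None, rule: Mapping[str, str] | None
) -> TargetClass:
    if rule and name is not None and name in rule:
        return TargetClass(rule[name])
    return TargetClass.ON_TARGET


def read_windows(
    path: str | Path,
    target_class_rule: Mapping[str, str] | None = None,
) -> WindowSet:
    """Read windows from a BED3+ or GFF3 file.

    The format is chosen from the file extension (.gff/.gff3 → GFF3,
    otherwise BED). GFF3 1-based closed coordinates are converted to the
    internal 0-based half-open convention. ``target_class_rule`` maps the BED
    name column / GFF3 ``target_class`` or ``Name`` attribute to a class
    ("on_target", "off_target", "control"); unmapped windows default to
    on_target.
    """
    path = Path(path)
    is_gff = path.suffix.lower() in {".gff", ".gff3"}
    windows: list[GenomicWindow] = []
    auto_id = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            try:
                if is_gff:
                    if len(fields) < 9:
                        raise ParseError(
                            f"{path}:{lineno}: GFF3 line has "
                            f"{len(fields)} fields, expected 9"
                        )
                    chrom = fields[0]
                    start = int(fields[3]) - 1
                    end = int(fields[4])
                    attrs = dict(
                        kv.split("=", 1)
                        for kv in fields[8].split(";")
                        if "=" in kv
                    )
                    name = attrs.get("ID") or attrs.get("Name")
                    cls_key = attrs.get("target_class") or attrs.get("Name")
                else:
                    if len(fields) < 3:
                        raise ParseError(
                            f"{path}:{lineno}: BED line has "
                            f"{len(fields)} fields, expected >= 3"
                        )
                    chrom = fields[0]
                    start = int(fields[1])
                    end = int(fields[2])
                    name = fields[3] if len(fields) > 3 else None
                    cls_key = name
            except ParseError:
                raise
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if name is None:
                auto_id += 1
                name = f"window_{auto_id:05d}"
            if end <= start:
                raise ValidationError(
                    f"{path}:{lineno}: window {name!r} has end <= start"
                )
            windows.append(
                GenomicWindow(
                    chrom=chrom,
                    start=start,
                    end=end,
                    window_id=name,
                    target_class=_parse_target_class(cls_key, target_class_rule),
                )
            )
    return WindowSet(windows)


def write_bed(windows: WindowSet, path: str | Path) -> None:
    """Write windows as BED4 (name column = window_id)."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.window_id}\n")


def read_control_file(path: str | Path) -> "WindowSet | list[str]":
    """Read a control-window file: BED4, or one window_id per line.

    Auto-detected: lines with >= 3 tab-separated fields where fields 2-3 are
    integers are treated as BED; otherwise the file is an id list.
    """
    path = Path(path)
    lines = [
        ln.rstrip("\n")
        for ln in open(path)
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise ValidationError(f"{path}: empty control-window file")

    def _is_bed(line: str) -> bool:
        f = line.split("\t")
        if len(f) < 3:
            return False
        try:
            int(f[1]), int(f[2])
        except ValueError:
            return False
        return True

    if all(_is_bed(ln) for ln in lines):
        return read_windows(path)
    return [ln.split("\t")[0] for ln in lines]
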