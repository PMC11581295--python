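"""The ordered match lexicon driving the string-matching classifier.

Rules are plain text so the keyword list can be audited and extended
without touching code: one rule per line with axis, priority, regex
pattern, and target label.  Patterns are matched case-insensitively
against normalized sentence text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from . import vocab
from .records import InputError

AXES = ("category", "subtype", "primary_site", "location")

_AXIS_VOCAB = {
    "category": set(vocab.CATEGORIES),
    "subtype": set(vocab.SUBTYPES) | {vocab.SUBTYPE_OTHER},
    "primary_site": set(vocab.PRIMARY_SITES),
    "location": set(vocab.SITES[:-1]),  # unknown is a fallback, never matched
}


@dataclass(frozen=True)
class MatchRule:
    axis: str
    priority: int
    pattern: str
    label: str

    def compiled(self) -> re.Pattern:
        return re.compile(self.pattern, re.IGNORECASE)


class MatchLexicon:
    """Ordered rule collection; higher priority wins within an axis."""

    def __init__(self, rules: list[MatchRule]):
        for axis in AXES:
            pri = [r.priority for r in rules if r.axis == axis]
            if len(pri) != len(set(pri)):
                raise InputError(f"duplicate priorities on axis {axis!r}")
        for r in rules:
            if r.axis not in AXES:
                raise InputError(f"unknown axis {r.axis!r}")
            if r.label not in _AXIS_VOCAB[r.axis]:
                raise InputError(
                    f"label {r.label!r} outside the {r.axis} vocabulary"
                )
        self.rules = sorted(rules, key=lambda r: (r.axis, -r.priority))
        self._compiled = [(r, r.compiled()) for r in self.rules]

    def axis_rules(self, axis: str) -> list[tuple[MatchRule, re.Pattern]]:
        return [(r, c) for r, c in self._compiled if r.axis == axis]

    @classmethod
    def from_file(cls, path: str | Path) -> "MatchLexicon":
        rules = []
        for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise InputError(f"lexicon line {ln}: expected 4 tab-separated "
                                 f"fields, got {len(parts)}")
            axis, priority, pattern, label = parts
            rules.append(MatchRule(axis, int(priority), pattern, label))
        return cls(rules)

    def to_file(self, path: str | Path) -> None:
        lines = ["# axis\tpriority\tpattern\tlabel"]
        for r in self.rules:
            lines.append(f"{r.axis}\t{r.priority}\t{r.pattern}\t{r.label}")
        Path(path).write_text("\n".join(lines) + "\n")


def default_lexicon() -> MatchLexicon:
    """The lexicon shipped with the package."""
    ref = resources.files("lungbm").joinpath("data/lexicon.tsv")
    with resources.as_file(ref) as path:
        return MatchLexicon.from_file(path)
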