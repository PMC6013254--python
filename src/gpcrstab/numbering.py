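"""Generic residue numbering and canonical mutation records.

Class-A GPCRs are compared across receptors through the GPCRdb
(Ballesteros–Weinstein) generic numbering scheme, written ``tm.offset``
(e.g. ``7.45``), where ``tm`` is the helix index (1–7, 8 for helix 8)
and ``offset`` positions the residue relative to the helix's most
conserved residue at ``x.50``.  This module holds the mapping between a
receptor's 1-based sequence positions and generic numbers, plus the
canonical mutation labels used in reports (``C360^7.45^N``,
``A98^2.49^C/A140^3.38^C`` for engineered double-cysteine bridges).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_GN_RE = re.compile(r"^(\d+)\.(\d+)$")
_SITE_RE = re.compile(r"^([A-Z])(\d+)\^([^^]+)\^([A-Z])$")


class NumberingError(ValueError):
    """Malformed generic number, label, or annotation table."""


@dataclass(frozen=True, order=True)
class GenericNumber:
    """A GPCRdb generic position ``tm.offset`` on a TM helix (1-7) or helix 8."""

    tm_index: int
    offset: int

    def __post_init__(self) -> None:
        if not 1 <= self.tm_index <= 8:
            raise NumberingError(
                f"tm index {self.tm_index} outside the 7TM+H8 range 1-8"
            )
        if not 0 <= self.offset <= 99:
            raise NumberingError(f"offset {self.offset} outside 0-99")

    def __str__(self) -> str:
        return f"{self.tm_index}.{self.offset:02d}"


def parse_generic_number(text: str) -> GenericNumber:
    """Parse ``"7.45"`` into :class:`GenericNumber` ``(7, 45)``.

    Raises :class:`NumberingError` for malformed text or a helix index
    outside 1-8; intracellular/extracellular region tags ("12.51",
    "ECL2", ...) are deliberately not parseable and travel as opaque
    strings in :class:`ReceptorAnnotation`.
    """
    m = _GN_RE.match(text.strip())
    if m is None:
        raise NumberingError(f"malformed generic number {text!r}")
    return GenericNumber(int(m.group(1)), int(m.group(2)))


def try_parse_generic_number(text: str) -> GenericNumber | None:
    """Like :func:`parse_generic_number` but ``None`` for region tags."""
    try:
        return parse_generic_number(text)
    except NumberingError:
        return None


@dataclass(frozen=True)
class ReceptorAnnotation:
    """Target sequence plus its position → generic-number table.

    ``tm_map`` maps 1-based sequence positions to raw generic-number
    strings.  Entries that parse as ``tm.offset`` with helix index 1-8
    are TM positions; anything else (loop/terminus tags such as
    ``"ECL2"`` or ``"12.51"``) is carried opaquely and never scored.
    The table is an input: TM boundary inference is not performed here.
    """

    sequence: str
    tm_map: dict[int, str]
    name: str = "receptor"

    def __post_init__(self) -> None:
        n = len(self.sequence)
        seen_gn: dict[str, int] = {}
        for pos, gn in self.tm_map.items():
            if not 1 <= pos <= n:
                raise NumberingError(
                    f"annotated position {pos} outside sequence of length {n}"
                )
            if gn in seen_gn:
                raise NumberingError(
                    f"generic number {gn!r} assigned to both positions "
                    f"{seen_gn[gn]} and {pos}"
                )
            seen_gn[gn] = pos

    # -- lookups ---------------------------------------------------------

    def residue(self, position: int) -> str:
        return self.sequence[position - 1]

    def generic_number(self, position: int) -> str | None:
        return self.tm_map.get(position)

    def tm_number(self, position: int) -> GenericNumber | None:
        gn = self.tm_map.get(position)
        return try_parse_generic_number(gn) if gn is not None else None

    def tm_positions(self) -> list[int]:
        """Annotated positions carrying a TM (or helix-8) generic number."""
        return sorted(p for p in self.tm_map if self.tm_number(p) is not None)

    def resolve(self, gn: GenericNumber | str) -> tuple[int, str] | None:
        """Return ``(position, wt_aa)`` for a generic number, or ``None``."""
        key = str(gn)
        for pos, tag in self.tm_map.items():
            if tag == key:
                return pos, self.residue(pos)
        return None

    # -- TSV interface ---------------------------------------------------

    @classmethod
    def from_tsv(cls, path, name: str | None = None) -> "ReceptorAnnotation":
        """Read an annotation table (columns position, residue, generic_number)."""
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        required = {"position", "residue", "generic_number"}
        if not required.issubset(df.columns):
            raise NumberingError(
                f"annotation table must have columns {sorted(required)}"
            )
        df["position"] = df["position"].astype(int)
        df = df.sort_values("position")
        positions = df["position"].to_list()
        if len(set(positions)) != len(positions):
            raise NumberingError("duplicate positions in annotation table")
        if positions != list(range(1, len(positions) + 1)):
            raise NumberingError(
                "annotation table must list every sequence position once, 1..L"
            )
        sequence = "".join(df["residue"])
        tm_map = {
            int(r.position): r.generic_number
            for r in df.itertuples()
            if r.generic_number
        }
        return cls(sequence=sequence, tm_map=tm_map, name=name or "receptor")

    def to_tsv(self, path) -> None:
        rows = [
            (i + 1, aa, self.tm_map.get(i + 1, ""))
            for i, aa in enumerate(self.sequence)
        ]
        pd.DataFrame(rows, columns=["position", "residue", "generic_number"]).to_csv(
            path, sep="\t", index=False
        )


def resolve_position(
    annotation: ReceptorAnnotation, gn: GenericNumber | str
) -> tuple[int, str] | None:
    """Module-level alias for :meth:`ReceptorAnnotation.resolve`."""
    return annotation.resolve(gn)


@dataclass(frozen=True)
class MutationSite:
    position: int
    wt_aa: str
    mut_aa: str
    gn: str | None = None

    def __post_init__(self) -> None:
        if self.wt_aa == self.mut_aa:
            raise NumberingError(
                f"site {self.position}: wild-type and mutant residue both "
                f"{self.wt_aa!r}"
            )

    def __str__(self) -> str:
        gn = self.gn or "-"
        return f"{self.wt_aa}{self.position}^{gn}^{self.mut_aa}"


@dataclass(frozen=True)
class Mutation:
    """One or two substitutions; two sites only for engineered bridges."""

    sites: tuple[MutationSite, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.sites) <= 2:
            raise NumberingError("a mutation has one site, or two for a bridge")
        if len({s.position for s in self.sites}) != len(self.sites):
            raise NumberingError("bridge sites must be distinct positions")

    @property
    def label(self) -> str:
        return "/".join(str(s) for s in self.sites)

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(s.position for s in self.sites)

    def __str__(self) -> str:
        return self.label

    @classmethod
    def single(
        cls, position: int, wt_aa: str, mut_aa: str, gn: str | None = None
    ) -> "Mutation":
        return cls((MutationSite(position, wt_aa, mut_aa, gn),))

    @classmethod
    def from_label(cls, label: str) -> "Mutation":
        sites = []
        for token in label.split("/"):
            m = _SITE_RE.match(token.strip())
            if m is None:
                raise NumberingError(f"malformed mutation token {token!r}")
            wt, pos, gn, mut = m.groups()
            sites.append(MutationSite(int(pos), wt, mut, None if gn == "-" else gn))
        return cls(tuple(sites))

    def check_against(self, annotation: ReceptorAnnotation) -> None:
        for s in self.sites:
            actual = annotation.residue(s.position)
            if actual != s.wt_aa:
                raise NumberingError(
                    f"{self.label}: annotation has {actual} at {s.position}, "
                    f"not {s.wt_aa}"
                )


@dataclass
class ScoredMutation:
    """A candidate mutation with per-module scores and provenance."""

    mutation: Mutation
    module_scores: dict[str, float]
    provenance: list[str]
    final_score: float = float("nan")
    rank: int | None = None
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.provenance:
            raise NumberingError("provenance must name at least one module")
        missing = [m for m in self.provenance if m not in self.module_scores]
        if missing:
            raise NumberingError(f"provenance modules without scores: {missing}")

    @property
    def label(self) -> str:
        return self.mutation.label

    def with_flag(self, flag: str) -> "ScoredMutation":
        return replace(self, flags=self.flags | {flag})
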