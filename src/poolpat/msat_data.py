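"""Domain types and I/O for microsatellite parentage data.

Two kinds of records are handled: per-adult multilocus genotypes (an
unordered allele pair per locus, alleles labelled by fragment length in bp)
and per-egg-mass pooled allele sets (DNA from many embryos of one brood
extracted together, so only the union of alleles segregating in the brood
is observed, never individual offspring genotypes).

Alleles are categorical integer labels.  Fragment length carries no
quantitative meaning in any downstream inference; no arithmetic is ever
performed on allele values.

Missing-data semantics distinguish two states: ``ND`` (the sample was
genotyped but no call was obtained at that locus, e.g. low read depth) and
``NS`` (the individual was never sampled at all).
"""

from __future__ import annotations

import logging
import operator
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

logger = logging.getLogger("poolpat")

#: Literal used in mass tables for a locus with no genotype call.
NO_DATA = "ND"
#: Literal used for an individual that was never sampled.
NOT_SAMPLED = "NS"


class PanelFormatError(ValueError):
    """A table could not be parsed; the message names the row and column."""


class PanelValidationError(ValueError):
    """Parsed data violate a structural invariant of the panel."""


class SocialStatus(str, Enum):
    PAIRED = "paired"
    SOLITARY = "solitary"
    GROUPED = "grouped"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class Locus:
    """A named microsatellite marker.

    The repeat motif is informational (it documents the marker); only the
    locus name participates in inference.
    """

    name: str
    repeat_motif: str

    def __post_init__(self) -> None:
        if len(self.repeat_motif) not in (2, 3, 4):
            raise PanelValidationError(
                f"locus {self.name!r}: repeat motif {self.repeat_motif!r} must "
                "be a di-, tri- or tetranucleotide"
            )

    @property
    def motif_length(self) -> int:
        return len(self.repeat_motif)


@dataclass(frozen=True)
class AdultGenotype:
    """One adult's multilocus genotype plus social metadata.

    ``calls`` maps locus name to a normalized (low, high) allele pair; a
    locus absent from ``calls`` is missing for this adult.
    """

    adult_id: str
    social_status: SocialStatus = SocialStatus.UNKNOWN
    shell_length_mm: Optional[float] = None
    calls: Mapping[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        norm = {}
        for locus, pair in self.calls.items():
            a, b = pair
            try:
                a, b = operator.index(a), operator.index(b)
            except TypeError:
                raise PanelValidationError(
                    f"adult {self.adult_id!r}, locus {locus!r}: alleles must be "
                    f"integers, got {pair!r}"
                ) from None
            if a <= 0 or b <= 0:
                raise PanelValidationError(
                    f"adult {self.adult_id!r}, locus {locus!r}: alleles must be "
                    f"positive integers, got {pair!r}"
                )
            norm[locus] = (a, b) if a <= b else (b, a)
        object.__setattr__(self, "calls", norm)
        if self.shell_length_mm is not None and not self.shell_length_mm > 0:
            raise PanelValidationError(
                f"adult {self.adult_id!r}: shell length must be positive"
            )

    def call(self, locus: str) -> Optional[tuple[int, int]]:
        return self.calls.get(locus)

    def alleles(self, locus: str) -> frozenset[int]:
        """Distinct alleles carried at ``locus`` (empty if missing)."""
        pair = self.calls.get(locus)
        return frozenset(pair) if pair is not None else frozenset()


@dataclass(frozen=True)
class EggMassRecord:
    """Pooled allele sets of one egg mass.

    ``alleles`` maps locus name to the set of detected alleles, or ``None``
    for a locus with no data (``ND``).  ``maternal_id`` may be the literal
    ``NS`` when the depositing adult was seen but never tissue-sampled.
    """

    mass_id: str
    maternal_id: str
    maternal_status: SocialStatus = SocialStatus.UNKNOWN
    putative_sire_id: Optional[str] = None
    alleles: Mapping[str, Optional[frozenset[int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        norm: dict[str, Optional[frozenset[int]]] = {}
        for locus, aset in self.alleles.items():
            if aset is None:
                norm[locus] = None
                continue
            aset = frozenset(int(a) for a in aset)
            if not aset:
                raise PanelValidationError(
                    f"mass {self.mass_id!r}, locus {locus!r}: allele set is "
                    "empty; use NO_DATA (None) for a locus without data"
                )
            if any(a <= 0 for a in aset):
                raise PanelValidationError(
                    f"mass {self.mass_id!r}, locus {locus!r}: alleles must be "
                    "positive integers"
                )
            norm[locus] = aset
        object.__setattr__(self, "alleles", norm)

    @property
    def maternal_sampled(self) -> bool:
        return self.maternal_id != NOT_SAMPLED

    def informative_loci(self) -> list[str]:
        return [l for l, s in self.alleles.items() if s is not None]


@dataclass(frozen=True)
class Panel:
    """A marker panel together with the adults and egg masses typed on it."""

    loci: tuple[Locus, ...]
    adults: tuple[AdultGenotype, ...] = ()
    masses: tuple[EggMassRecord, ...] = ()

    def __post_init__(self) -> None:
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise PanelValidationError("duplicate locus names in panel")
        ids = [a.adult_id for a in self.adults]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PanelValidationError(f"duplicate adult_id(s): {dupes}")
        known = set(names)
        for a in self.adults:
            extra = set(a.calls) - known
            if extra:
                raise PanelValidationError(
                    f"adult {a.adult_id!r} has calls at unknown loci {sorted(extra)}"
                )
        by_id = {a.adult_id: a for a in self.adults}
        for m in self.masses:
            extra = set(m.alleles) - known
            if extra:
                raise PanelValidationError(
                    f"mass {m.mass_id!r} has allele sets at unknown loci {sorted(extra)}"
                )
            if m.maternal_sampled and m.maternal_id not in by_id:
                raise PanelValidationError(
                    f"mass {m.mass_id!r}: maternal_id {m.maternal_id!r} does not "
                    f"resolve to a sampled adult (use {NOT_SAMPLED!r} if unsampled)"
                )

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    def adult(self, adult_id: str) -> Optional[AdultGenotype]:
        for a in self.adults:
            if a.adult_id == adult_id:
                return a
        return None

    def adult_alleles(self, locus: str) -> frozenset[int]:
        """Union of alleles observed at ``locus`` across all adults."""
        out: set[int] = set()
        for a in self.adults:
            out |= a.alleles(locus)
        return frozenset(out)


@dataclass(frozen=True)
class MaternalViolation:
    """An egg-mass allele set sharing no allele with the known mother."""

    mass_id: str
    locus: str
    mass_alleles: frozenset[int]
    maternal_alleles: frozenset[int]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _parse_int(value, row_label: str, column: str) -> int:
    try:
        f = float(value)
        i = int(f)
        if i != f:
            raise ValueError
        return i
    except (TypeError, ValueError):
        raise PanelFormatError(
            f"row {row_label!r}, column {column!r}: expected an integer allele, "
            f"got {value!r}"
        ) from None


def _is_blank(value) -> bool:
    return value is None or (isinstance(value, float) and pd.isna(value)) or (
        isinstance(value, str) and value.strip() == ""
    )


def read_loci(path: Path | str) -> list[Locus]:
    df = pd.read_csv(path, dtype=str)
    for col in ("locus", "repeat_motif"):
        if col not in df.columns:
            raise PanelFormatError(f"locus table {path}: missing column {col!r}")
    return [
        Locus(name=str(r["locus"]).strip(), repeat_motif=str(r["repeat_motif"]).strip())
        for _, r in df.iterrows()
    ]


def read_adults(path: Path | str, loci: Iterable[Locus]) -> list[AdultGenotype]:
    df = pd.read_csv(path, dtype=str)
    required = {"adult_id", "social_status", "shell_length_mm"}
    missing = required - set(df.columns)
    if missing:
        raise PanelFormatError(f"adult table {path}: missing columns {sorted(missing)}")
    adults = []
    for _, row in df.iterrows():
        aid = str(row["adult_id"]).strip()
        status = SocialStatus(str(row["social_status"]).strip().lower()) if not _is_blank(
            row["social_status"]
        ) else SocialStatus.UNKNOWN
        length = None if _is_blank(row["shell_length_mm"]) else float(row["shell_length_mm"])
        calls = {}
        for locus in loci:
            ca, cb = f"{locus.name}_a", f"{locus.name}_b"
            if ca not in df.columns or cb not in df.columns:
                continue
            va, vb = row[ca], row[cb]
            if _is_blank(va) and _is_blank(vb):
                continue
            if _is_blank(va) or _is_blank(vb):
                raise PanelFormatError(
                    f"row {aid!r}, column {ca if _is_blank(va) else cb!r}: "
                    "half-missing genotype (one allele blank)"
                )
            calls[locus.name] = (_parse_int(va, aid, ca), _parse_int(vb, aid, cb))
        adults.append(
            AdultGenotype(adult_id=aid, social_status=status, shell_length_mm=length, calls=calls)
        )
    return adults


def read_masses(path: Path | str, loci: Iterable[Locus]) -> list[EggMassRecord]:
    df = pd.read_csv(path, dtype=str)
    required = {"mass_id", "maternal_id", "maternal_status", "putative_sire_id"}
    missing = required - set(df.columns)
    if missing:
        raise PanelFormatError(f"mass table {path}: missing columns {sorted(missing)}")
    masses = []
    for _, row in df.iterrows():
        mid = str(row["mass_id"]).strip()
        alleles: dict[str, Optional[frozenset[int]]] = {}
        for locus in loci:
            if locus.name not in df.columns:
                continue
            cell = row[locus.name]
            if _is_blank(cell) or str(cell).strip() == NO_DATA:
                alleles[locus.name] = None
                continue
            parts = [p for p in str(cell).split(";") if p.strip()]
            alleles[locus.name] = frozenset(
                _parse_int(p.strip(), mid, locus.name) for p in parts
            )
        masses.append(
            EggMassRecord(
                mass_id=mid,
                maternal_id=str(row["maternal_id"]).strip(),
                maternal_status=SocialStatus(str(row["maternal_status"]).strip().lower())
                if not _is_blank(row["maternal_status"])
                else SocialStatus.UNKNOWN,
                putative_sire_id=None
                if _is_blank(row["putative_sire_id"])
                else str(row["putative_sire_id"]).strip(),
                alleles=alleles,
            )
        )
    return masses


def read_panel(
    adult_table_path: Path | str,
    mass_table_path: Path | str,
    locus_table_path: Path | str,
) -> Panel:
    """Read and validate a full panel from its three CSV tables."""
    loci = read_loci(locus_table_path)
    adults = read_adults(adult_table_path, loci)
    masses = read_masses(mass_table_path, loci)
    return Panel(loci=tuple(loci), adults=tuple(adults), masses=tuple(masses))


def write_panel(panel: Panel, out_dir: Path | str) -> dict[str, Path]:
    """Write a panel back to ``loci.csv``/``adults.csv``/``masses.csv``.

    The written files round-trip: reading them back yields an equal Panel.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "loci": out / "loci.csv",
        "adults": out / "adults.csv",
        "masses": out / "masses.csv",
    }
    pd.DataFrame(
        [{"locus": l.name, "repeat_motif": l.repeat_motif} for l in panel.loci]
    ).to_csv(paths["loci"], index=False)

    adult_rows = []
    for a in panel.adults:
        row: dict[str, object] = {
            "adult_id": a.adult_id,
            "social_status": a.social_status.value,
            "shell_length_mm": "" if a.shell_length_mm is None else a.shell_length_mm,
        }
        for name in panel.locus_names:
            pair = a.call(name)
            row[f"{name}_a"] = "" if pair is None else pair[0]
            row[f"{name}_b"] = "" if pair is None else pair[1]
        adult_rows.append(row)
    pd.DataFrame(adult_rows).to_csv(paths["adults"], index=False)

    mass_rows = []
    for m in panel.masses:
        row = {
            "mass_id": m.mass_id,
            "maternal_id": m.maternal_id,
            "maternal_status": m.maternal_status.value,
            "putative_sire_id": "" if m.putative_sire_id is None else m.putative_sire_id,
        }
        for name in panel.locus_names:
            aset = m.alleles.get(name)
            row[name] = NO_DATA if aset is None else ";".join(str(a) for a in sorted(aset))
        mass_rows.append(row)
    pd.DataFrame(mass_rows).to_csv(paths["masses"], index=False)
    return paths


def load_bundled_panel() -> Panel:
    """The worked-example dataset shipped with the package (see data/README.md)."""
    base = resources.files("poolpat") / "data"
    with resources.as_file(base) as d:
        return read_panel(d / "adults.csv", d / "masses.csv", d / "loci.csv")


# ---------------------------------------------------------------------------
# Validation / filtering
# ---------------------------------------------------------------------------

def validate_maternal_consistency(panel: Panel) -> list[MaternalViolation]:
    """Check that every egg mass shares ≥1 allele with its known mother at
    every locus with data.

    A violation at any locus indicates a transcription error, a genotyping
    failure, or a wrongly attributed mass.  Masses with unsampled mothers
    and loci without data are skipped.
    """
    violations = []
    for m in panel.masses:
        if not m.maternal_sampled:
            continue
        mother = panel.adult(m.maternal_id)
        if mother is None:
            continue
        for locus, aset in m.alleles.items():
            if aset is None:
                continue
            mat = mother.alleles(locus)
            if not mat:
                continue
            if not (aset & mat):
                violations.append(
                    MaternalViolation(m.mass_id, locus, aset, mat)
                )
    return violations


def filter_alleles_to_adult_panel(panel: Panel) -> Panel:
    """Drop egg-mass alleles not carried by any adult in the panel.

    Pooled-sample microsatellite calls can include PCR artifacts; restricting
    scored alleles to those observed in at least one adult is a conservative
    guard against artifactual alleles.  Removals are logged.  If a locus
    loses all its alleles it becomes NO_DATA, with a warning.  The operation
    is idempotent and monotone in the adult set.
    """
    adult_sets = {name: panel.adult_alleles(name) for name in panel.locus_names}
    new_masses = []
    for m in panel.masses:
        new_alleles: dict[str, Optional[frozenset[int]]] = {}
        for locus, aset in m.alleles.items():
            if aset is None:
                new_alleles[locus] = None
                continue
            kept = aset & adult_sets[locus]
            removed = aset - kept
            if removed:
                logger.info(
                    "mass %s, locus %s: removed allele(s) %s absent from the adult panel",
                    m.mass_id, locus, sorted(removed),
                )
            if not kept:
                logger.warning(
                    "mass %s, locus %s: all alleles removed by the adult-panel "
                    "filter; locus set to NO_DATA", m.mass_id, locus,
                )
                new_alleles[locus] = None
            else:
                new_alleles[locus] = kept
        new_masses.append(replace(m, alleles=new_alleles))
    return replace(panel, masses=tuple(new_masses))
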