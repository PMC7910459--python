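"""Dual-promoter paired-gRNA library data model.

A library couples two U6 promoters (hU6, sU6) on one lentiviral cassette so
that a single construct expresses two guides and disrupts two genes in the
same cell.  Two construct kinds exist:

* ``paired`` — guide against gene A under hU6, guide against gene B under
  sU6, in a single fixed orientation.
* ``single_targeting`` — a non-targeting control guide (Fluc) under hU6 and
  the targeting guide under sU6; measures the single-gene fitness effect.

For every gene pair the paired constructs are the full cross product of the
guide sets of the two genes (3–5 guides per gene), and every targeting guide
additionally appears in exactly one single-targeting construct.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "CONTROL_GENE",
    "FLUC_SPACER",
    "Guide",
    "Construct",
    "GenePair",
    "GuideLibrary",
    "LibraryError",
    "enumerate_constructs",
    "load_library",
    "write_library",
    "validate_library",
]

#: Reserved gene symbol for the non-targeting control guide.
CONTROL_GENE = "CONTROL"

#: Firefly-luciferase non-targeting spacer shipped as the default control
#: (stored without its NGG PAM).
FLUC_SPACER = "GTGTTGGGCGCGTTATTTAT"

PAIR_CATEGORIES = ("paralogue", "mutual_exclusivity", "synlethdb", "other")

_SPACER_ALPHABET = set("ACGT")


class LibraryError(ValueError):
    """Structured parse/validation error; carries row and field context."""

    def __init__(self, message: str, row: int | None = None, field: str | None = None):
        ctx = ""
        if row is not None:
            ctx += f" [row {row}]"
        if field is not None:
            ctx += f" [field {field}]"
        super().__init__(message + ctx)
        self.row = row
        self.field = field


@dataclass(frozen=True)
class Guide:
    guide_id: str
    gene: str
    spacer: str
    is_control: bool = False

    def __post_init__(self):
        if not self.spacer or not (19 <= len(self.spacer) <= 20):
            raise LibraryError(
                f"guide {self.guide_id!r}: spacer must be 19-20 nt, got "
                f"{len(self.spacer)}", field="spacer")
        if set(self.spacer) - _SPACER_ALPHABET:
            raise LibraryError(
                f"guide {self.guide_id!r}: spacer contains characters outside "
                f"A/C/G/T: {self.spacer}", field="spacer")
        if self.is_control and self.gene != CONTROL_GENE:
            raise LibraryError(
                f"control guide {self.guide_id!r} must use the reserved gene "
                f"symbol {CONTROL_GENE!r}", field="gene")


@dataclass(frozen=True)
class Construct:
    construct_id: str
    hu6_guide: str
    su6_guide: str
    kind: str  # "paired" | "single_targeting"

    def __post_init__(self):
        if self.kind not in ("paired", "single_targeting"):
            raise LibraryError(
                f"construct {self.construct_id!r}: unknown kind {self.kind!r}",
                field="kind")


@dataclass(frozen=True)
class GenePair:
    """Unordered gene pair, stored in canonical lexicographic order."""

    gene_a: str
    gene_b: str
    category: str = "other"

    def __post_init__(self):
        if self.gene_a == self.gene_b:
            raise LibraryError(f"gene pair members must differ: {self.gene_a}")
        if self.gene_a > self.gene_b:
            a, b = self.gene_b, self.gene_a
            object.__setattr__(self, "gene_a", a)
            object.__setattr__(self, "gene_b", b)
        if self.category not in PAIR_CATEGORIES:
            raise LibraryError(
                f"unknown pair category {self.category!r}", field="category")

    @property
    def key(self) -> str:
        return f"{self.gene_a}|{self.gene_b}"


@dataclass
class GuideLibrary:
    guides: dict[str, Guide] = field(default_factory=dict)
    pairs: dict[str, GenePair] = field(default_factory=dict)
    constructs: dict[str, Construct] = field(default_factory=dict)
    control_guide_id: str | None = None

    # -- lookups -----------------------------------------------------------
    def guide(self, guide_id: str) -> Guide:
        try:
            return self.guides[guide_id]
        except KeyError:
            raise LibraryError(f"unknown guide_id {guide_id!r}") from None

    def construct_genes(self, construct: Construct) -> tuple[str, str]:
        """Genes targeted by (hu6, su6) slots (control slot -> CONTROL)."""
        return (self.guide(construct.hu6_guide).gene,
                self.guide(construct.su6_guide).gene)

    def pair_of(self, construct: Construct) -> GenePair:
        """The GenePair a paired construct belongs to."""
        if construct.kind != "paired":
            raise LibraryError(
                f"construct {construct.construct_id!r} is not paired")
        a, b = self.construct_genes(construct)
        key = GenePair(a, b).key
        try:
            return self.pairs[key]
        except KeyError:
            raise LibraryError(
                f"construct {construct.construct_id!r}: genes ({a}, {b}) do "
                f"not form a registered pair") from None

    def single_targeting_construct(self, guide_id: str) -> Construct:
        """The unique control+guide construct carrying this targeting guide."""
        matches = [c for c in self.constructs.values()
                   if c.kind == "single_targeting" and c.su6_guide == guide_id]
        if len(matches) != 1:
            raise LibraryError(
                f"guide {guide_id!r} has {len(matches)} single-targeting "
                f"constructs; expected exactly 1")
        return matches[0]

    def paired_constructs(self) -> list[Construct]:
        return [c for c in self.constructs.values() if c.kind == "paired"]

    def single_constructs(self) -> list[Construct]:
        return [c for c in self.constructs.values()
                if c.kind == "single_targeting"]

    def guides_for_gene(self, gene: str) -> list[Guide]:
        return sorted((g for g in self.guides.values() if g.gene == gene),
                      key=lambda g: g.guide_id)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GuideLibrary):
            return NotImplemented
        return (self.guides == other.guides and self.pairs == other.pairs
                and self.constructs == other.constructs
                and self.control_guide_id == other.control_guide_id)


# ---------------------------------------------------------------------------
# construction


def enumerate_constructs(guides_a: list[Guide], guides_b: list[Guide],
                         control: Guide,
                         smaller_gene_in_hu6: bool = True) -> list[Construct]:
    """Enumerate all constructs for one gene pair.

    Returns ``|A|*|B|`` paired constructs (one fixed orientation: the gene in
    the hU6 slot crossed with the gene in the sU6 slot) followed by
    ``|A|+|B|`` single-targeting constructs (control under hU6, targeting
    guide under sU6), in deterministic order.

    By default the gene with the lexicographically smaller symbol takes the
    hU6 slot; set ``smaller_gene_in_hu6=False`` to flip the convention.
    """
    if not guides_a or not guides_b:
        raise LibraryError("each gene needs at least one guide")
    if len(guides_a) > 5 or len(guides_b) > 5:
        raise LibraryError("at most 5 guides per gene are supported")
    if not control.is_control:
        raise LibraryError(
            f"guide {control.guide_id!r} is not flagged as a control")
    gene_a = guides_a[0].gene
    gene_b = guides_b[0].gene
    if any(g.gene != gene_a for g in guides_a) or \
       any(g.gene != gene_b for g in guides_b):
        raise LibraryError("guide lists must each target a single gene")
    if gene_a == gene_b:
        raise LibraryError("the two guide sets must target different genes")

    hu6_set, su6_set = (guides_a, guides_b)
    if (gene_a > gene_b) == smaller_gene_in_hu6:
        hu6_set, su6_set = su6_set, hu6_set

    out: list[Construct] = []
    for ga, gb in itertools.product(hu6_set, su6_set):
        out.append(Construct(
            construct_id=f"{ga.guide_id}__{gb.guide_id}",
            hu6_guide=ga.guide_id, su6_guide=gb.guide_id, kind="paired"))
    for g in itertools.chain(guides_a, guides_b):
        out.append(Construct(
            construct_id=f"{control.guide_id}__{g.guide_id}",
            hu6_guide=control.guide_id, su6_guide=g.guide_id,
            kind="single_targeting"))
    return out


def build_library(pair_guides: dict[GenePair, tuple[list[Guide], list[Guide]]],
                  control: Guide) -> GuideLibrary:
    """Assemble a full GuideLibrary from per-pair guide sets.

    A targeting guide may belong to only one gene; its single-targeting
    construct is emitted once even if the gene sits in several pairs.
    """
    lib = GuideLibrary(control_guide_id=control.guide_id)
    lib.guides[control.guide_id] = control
    for pair, (ga, gb) in pair_guides.items():
        lib.pairs[pair.key] = pair
        for g in itertools.chain(ga, gb):
            existing = lib.guides.get(g.guide_id)
            if existing is not None and existing != g:
                raise LibraryError(f"conflicting definitions for guide "
                                   f"{g.guide_id!r}")
            lib.guides[g.guide_id] = g
        for c in enumerate_constructs(ga, gb, control):
            lib.constructs.setdefault(c.construct_id, c)
    return lib


# ---------------------------------------------------------------------------
# persistence — one TSV with a record_type column

_COLUMNS = ["record_type", "guide_id", "gene", "spacer", "is_control",
            "construct_id", "hu6_guide", "su6_guide", "kind",
            "gene_b", "category"]


def write_library(lib: GuideLibrary, path) -> None:
    """Write a library as a single UTF-8 TSV with a record_type column."""
    rows = []
    for g in sorted(lib.guides.values(), key=lambda g: g.guide_id):
        rows.append({"record_type": "guide", "guide_id": g.guide_id,
                     "gene": g.gene, "spacer": g.spacer,
                     "is_control": str(g.is_control).lower()})
    for p in sorted(lib.pairs.values(), key=lambda p: p.key):
        rows.append({"record_type": "pair", "gene": p.gene_a,
                     "gene_b": p.gene_b, "category": p.category})
    for c in sorted(lib.constructs.values(), key=lambda c: c.construct_id):
        rows.append({"record_type": "construct", "construct_id": c.construct_id,
                     "hu6_guide": c.hu6_guide, "su6_guide": c.su6_guide,
                     "kind": c.kind})
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


def load_library(path) -> GuideLibrary:
    """Load a library TSV written by :func:`write_library`.

    Raises :class:`LibraryError` naming the offending row and field on
    missing columns, unknown guide references, malformed spacers, or
    duplicate rows.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"record_type", "guide_id", "gene", "spacer", "is_control",
                "construct_id", "hu6_guide", "su6_guide", "kind"}
    missing = required - set(df.columns)
    if missing:
        raise LibraryError(f"missing columns: {sorted(missing)}")

    lib = GuideLibrary()
    for i, row in df.iterrows():
        rownum = i + 2  # 1-based, counting the header
        rtype = row["record_type"]
        if rtype == "guide":
            is_control = row["is_control"].strip().lower() in ("true", "1", "yes")
            try:
                g = Guide(row["guide_id"], row["gene"], row["spacer"],
                          is_control)
            except LibraryError as e:
                raise LibraryError(str(e), row=rownum) from None
            if g.guide_id in lib.guides:
                raise LibraryError(f"duplicate guide_id {g.guide_id!r}",
                                   row=rownum, field="guide_id")
            lib.guides[g.guide_id] = g
            if is_control:
                lib.control_guide_id = g.guide_id
        elif rtype == "pair":
            cat = row.get("category", "") or "other"
            p = GenePair(row["gene"], row["gene_b"], cat)
            if p.key in lib.pairs:
                raise LibraryError(f"duplicate gene pair {p.key!r}", row=rownum)
            lib.pairs[p.key] = p
        elif rtype == "construct":
            for col in ("hu6_guide", "su6_guide"):
                if row[col] not in lib.guides:
                    raise LibraryError(
                        f"construct {row['construct_id']!r} references "
                        f"undefined guide_id {row[col]!r}",
                        row=rownum, field=col)
            c = Construct(row["construct_id"], row["hu6_guide"],
                          row["su6_guide"], row["kind"])
            if c.construct_id in lib.constructs:
                raise LibraryError(f"duplicate construct_id "
                                   f"{c.construct_id!r}", row=rownum,
                                   field="construct_id")
            lib.constructs[c.construct_id] = c
        else:
            raise LibraryError(f"unknown record_type {rtype!r}", row=rownum,
                               field="record_type")
    return lib


# ---------------------------------------------------------------------------
# validation


def validate_library(lib: GuideLibrary) -> list[str]:
    """Report every library invariant violation; empty list <=> valid.

    Checks referential integrity, the promoter convention (control under hU6
    in single-targeting constructs; two distinct targeting genes in paired
    constructs), completeness of the guide x guide cross product for every
    pair, one single-targeting construct per targeting guide, and that every
    paired construct's genes form a registered pair.
    """
    report: list[str] = []
    control_id = lib.control_guide_id
    if control_id is None or control_id not in lib.guides:
        report.append("no control guide defined")
        control_id = None

    for c in lib.constructs.values():
        for col, gid in (("hu6_guide", c.hu6_guide), ("su6_guide", c.su6_guide)):
            if gid not in lib.guides:
                report.append(
                    f"construct {c.construct_id}: {col} {gid!r} undefined")
        if not (c.hu6_guide in lib.guides and c.su6_guide in lib.guides):
            continue
        hu6, su6 = lib.guide(c.hu6_guide), lib.guide(c.su6_guide)
        if c.kind == "single_targeting":
            if not hu6.is_control:
                report.append(
                    f"construct {c.construct_id}: single_targeting must carry "
                    f"the control guide under hU6, found {hu6.guide_id!r}")
            if su6.is_control:
                report.append(
                    f"construct {c.construct_id}: sU6 slot of a "
                    f"single_targeting construct must target a gene")
        else:
            if hu6.is_control or su6.is_control:
                report.append(
                    f"construct {c.construct_id}: paired construct must not "
                    f"carry the control guide")
            elif hu6.gene == su6.gene:
                report.append(
                    f"construct {c.construct_id}: paired construct targets "
                    f"{hu6.gene} twice")
            else:
                key = GenePair(hu6.gene, su6.gene).key
                if key not in lib.pairs:
                    report.append(
                        f"construct {c.construct_id}: genes {key} are not a "
                        f"registered pair")

    # completeness of the guide x guide product per pair
    paired_index = {}
    for c in lib.paired_constructs():
        if c.hu6_guide in lib.guides and c.su6_guide in lib.guides:
            paired_index[(c.hu6_guide, c.su6_guide)] = c
    for p in lib.pairs.values():
        ga = lib.guides_for_gene(p.gene_a)
        gb = lib.guides_for_gene(p.gene_b)
        for g1, g2 in itertools.product(ga, gb):
            present = ((g1.guide_id, g2.guide_id) in paired_index
                       or (g2.guide_id, g1.guide_id) in paired_index)
            if not present:
                report.append(
                    f"pair {p.key}: missing paired construct for guides "
                    f"({g1.guide_id}, {g2.guide_id})")

    # one single-targeting construct per targeting guide
    singles: dict[str, int] = {}
    for c in lib.single_constructs():
        singles[c.su6_guide] = singles.get(c.su6_guide, 0) + 1
    for g in lib.guides.values():
        if g.is_control:
            continue
        n = singles.get(g.guide_id, 0)
        if n != 1:
            report.append(
                f"guide {g.guide_id}: {n} single-targeting constructs, "
                f"expected exactly 1")

    # orphan guides (targeting guides used by no construct at all)
    used = {c.hu6_guide for c in lib.constructs.values()} | \
           {c.su6_guide for c in lib.constructs.values()}
    for g in lib.guides.values():
        if not g.is_control and g.guide_id not in used:
            report.append(f"guide {g.guide_id}: orphan (no construct uses it)")
    return report
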