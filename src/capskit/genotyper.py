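"""Marker panels, assay simulation per query, and allele calling.

A panel is an ordered list of markers (CAPS/dCAPS/STS, optionally nested)
plus a profile table mapping each known allele to its expected outcome
vector — the in-silico equivalent of a "which bands do I expect on the
gel" table.  Running the panel on a query sequence produces an observed
vector; the call is ``unique`` when exactly one profile row matches under
the configured gel resolution, ``ambiguous``/``inconsistent`` otherwise,
and ``no_amplification`` when nothing amplified at all.  Absence of a
product is a legitimate diagnostic state (a primer pair straddling a large
retrotransposon insertion yields no first-round product), so profile rows
can require it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence

import yaml

from .enzymes import (
    EnzymeError,
    FragmentProfile,
    RestrictionEnzyme,
    default_enzyme_library,
    digest,
    resolve_enzyme,
)
from .ispcr import Amplicon, BindingModel, Primer, amplify, nested_amplify
from .seqcore import AlleleRecord

__all__ = [
    "GelResolution",
    "ExpectedOutcome",
    "MarkerOutcome",
    "MarkerDefinition",
    "MarkerPanel",
    "GenotypeCall",
    "PanelError",
    "comigrate",
    "run_marker",
    "call_alleles",
    "validate_panel",
    "load_panel",
    "save_panel",
]


class PanelError(ValueError):
    """Structurally invalid marker panel."""


@dataclass(frozen=True)
class GelResolution:
    """Agarose co-migration threshold: two fragments are indistinguishable
    when their difference is within max(floor_bp, fraction * mean length)."""

    floor_bp: int = 10
    fraction: float = 0.05


def comigrate(len_a: int, len_b: int, resolution: GelResolution) -> bool:
    """True iff two fragment lengths would co-migrate on the gel."""
    if len_a < 1 or len_b < 1:
        raise ValueError("fragment lengths must be >= 1")
    tol = max(resolution.floor_bp, resolution.fraction * (len_a + len_b) / 2.0)
    return abs(len_a - len_b) <= tol


#: sentinel accepted in expected-outcome cells
ANY = "any"


@dataclass
class ExpectedOutcome:
    """One cell of the profile table: the outcome a marker should show for
    one allele.  Each field may be ``"any"`` (no constraint) — used for
    table cells that are not diagnostic for the row."""

    product: bool | str = ANY
    cut: bool | str = ANY
    product_length: int | str = ANY
    fragments: tuple[int, ...] | str = ANY


@dataclass
class MarkerOutcome:
    """Observed outcome of one marker on one query."""

    marker: str
    state: str  # "product" | "no_amplification"
    product_lengths: tuple[int, ...] = ()
    fragments: Optional[tuple[int, ...]] = None

    @property
    def is_cut(self) -> Optional[bool]:
        if self.fragments is None:
            return None
        return len(self.fragments) > 1


@dataclass
class MarkerDefinition:
    """One assay of the panel.

    CAPS/dCAPS markers must name an enzyme, STS markers must not; nested
    markers reference an outer primer pair whose product serves as the
    second-round template.
    """

    name: str
    marker_type: str  # "CAPS" | "dCAPS" | "STS"
    fwd: Primer
    rev: Primer
    enzyme: Optional[str] = None
    outer_pair: Optional[tuple[Primer, Primer]] = None

    def __post_init__(self) -> None:
        if self.marker_type not in ("CAPS", "dCAPS", "STS"):
            raise PanelError(f"marker {self.name}: unknown type {self.marker_type!r}")
        if self.marker_type in ("CAPS", "dCAPS") and not self.enzyme:
            raise PanelError(f"marker {self.name}: {self.marker_type} needs an enzyme")
        if self.marker_type == "STS" and self.enzyme:
            raise PanelError(f"marker {self.name}: STS markers take no enzyme")


@dataclass
class MarkerPanel:
    """Ordered markers + per-allele expected profiles + run parameters."""

    markers: list[MarkerDefinition]
    profile_table: dict[str, dict[str, ExpectedOutcome]]
    model: BindingModel = field(default_factory=BindingModel)
    gel_resolution: GelResolution = field(default_factory=GelResolution)
    enzyme_library: list[RestrictionEnzyme] = field(
        default_factory=default_enzyme_library
    )

    def marker(self, name: str) -> MarkerDefinition:
        for m in self.markers:
            if m.name == name:
                return m
        raise PanelError(f"no marker named {name!r}")


@dataclass
class GenotypeCall:
    """The verdict for one query: which allele rows match the evidence."""

    query_id: str
    called_alleles: list[str]
    status: str  # "unique" | "ambiguous" | "inconsistent" | "no_amplification"
    evidence: dict[str, MarkerOutcome]


def run_marker(
    marker: MarkerDefinition,
    query: AlleleRecord,
    model: BindingModel,
    library: Sequence[RestrictionEnzyme] | None = None,
) -> MarkerOutcome:
    """Simulate one marker on one query sequence.

    STS markers report amplicon lengths only; CAPS/dCAPS amplify (nested if
    an outer pair is defined) and digest the first product.  No product is
    reported as an explicit ``no_amplification`` outcome.
    """
    library = list(library) if library is not None else default_enzyme_library()
    if marker.outer_pair is not None:
        amps = nested_amplify(query, marker.outer_pair, (marker.fwd, marker.rev), model)
    else:
        amps = amplify(query, marker.fwd, marker.rev, model)
    if not amps:
        return MarkerOutcome(marker=marker.name, state="no_amplification")
    lengths = tuple(len(a) for a in amps)
    fragments: Optional[tuple[int, ...]] = None
    if marker.enzyme:
        enz = resolve_enzyme(marker.enzyme, library)
        fragments = digest(amps[0], enz).fragment_lengths
    return MarkerOutcome(
        marker=marker.name,
        state="product",
        product_lengths=lengths,
        fragments=fragments,
    )


def _fragments_match(
    observed: tuple[int, ...], expected: tuple[int, ...], res: GelResolution
) -> bool:
    if len(observed) != len(expected):
        return False
    return all(
        comigrate(o, e, res) for o, e in zip(sorted(observed), sorted(expected))
    )


def _cell_matches(
    expected: ExpectedOutcome, observed: MarkerOutcome, res: GelResolution
) -> bool:
    has_product = observed.state == "product"
    if expected.product != ANY and bool(expected.product) != has_product:
        return False
    if not has_product:
        # with no product there is nothing further to compare
        return True
    if expected.cut != ANY:
        if observed.is_cut is None or bool(expected.cut) != observed.is_cut:
            return False
    if expected.product_length != ANY:
        if not any(
            comigrate(pl, int(expected.product_length), res)
            for pl in observed.product_lengths
        ):
            return False
    if expected.fragments != ANY and expected.fragments is not None:
        if observed.fragments is None or not _fragments_match(
            observed.fragments, tuple(expected.fragments), res
        ):
            return False
    return True


def call_alleles(panel: MarkerPanel, query: AlleleRecord) -> GenotypeCall:
    """Run every marker of the panel on the query and match the observed
    outcome vector against the profile table row-wise."""
    evidence: dict[str, MarkerOutcome] = {}
    for marker in panel.markers:
        evidence[marker.name] = run_marker(
            marker, query, panel.model, panel.enzyme_library
        )
    matches = []
    for allele, row in panel.profile_table.items():
        if all(
            _cell_matches(
                row.get(m.name, ExpectedOutcome()),
                evidence[m.name],
                panel.gel_resolution,
            )
            for m in panel.markers
        ):
            matches.append(allele)
    if all(o.state == "no_amplification" for o in evidence.values()):
        status = "no_amplification"
    elif len(matches) == 1:
        status = "unique"
    elif len(matches) > 1:
        status = "ambiguous"
    else:
        status = "inconsistent"
    return GenotypeCall(
        query_id=query.id, called_alleles=matches, status=status, evidence=evidence
    )


# ---------------------------------------------------------------------------
# panel validation


@dataclass
class ValidationReport:
    defects: list[str]

    @property
    def ok(self) -> bool:
        return not self.defects


def _cells_compatible(
    a: ExpectedOutcome, b: ExpectedOutcome, res: GelResolution
) -> bool:
    """Could one observed outcome satisfy both expectations?"""
    if a.product != ANY and b.product != ANY and bool(a.product) != bool(b.product):
        return False
    if a.product is False or b.product is False:
        # one row expects no product: only the product flag can separate
        return True
    if a.cut != ANY and b.cut != ANY and bool(a.cut) != bool(b.cut):
        return False
    if (
        a.product_length != ANY
        and b.product_length != ANY
        and not comigrate(int(a.product_length), int(b.product_length), res)
    ):
        return False
    if (
        a.fragments not in (ANY, None)
        and b.fragments not in (ANY, None)
        and not _fragments_match(tuple(a.fragments), tuple(b.fragments), res)
    ):
        return False
    return True


def validate_panel(panel: MarkerPanel) -> ValidationReport:
    """Fail-fast structural checks: enzyme resolvability, nested outer
    pairs, profile coverage, and pairwise row distinguishability under the
    configured gel resolution."""
    defects: list[str] = []
    names = [m.name for m in panel.markers]
    if len(set(names)) != len(names):
        defects.append("duplicate marker names")
    for m in panel.markers:
        if m.enzyme:
            try:
                resolve_enzyme(m.enzyme, panel.enzyme_library)
            except EnzymeError as exc:
                defects.append(f"marker {m.name}: {exc}")
    alleles = list(panel.profile_table)
    if not alleles:
        defects.append("profile table is empty")
    for i, a in enumerate(alleles):
        for b in alleles[i + 1 :]:
            row_a, row_b = panel.profile_table[a], panel.profile_table[b]
            if all(
                _cells_compatible(
                    row_a.get(n, ExpectedOutcome()),
                    row_b.get(n, ExpectedOutcome()),
                    panel.gel_resolution,
                )
                for n in names
            ):
                defects.append(f"indistinguishable profiles: {a} vs {b}")
    return ValidationReport(defects=defects)


# ---------------------------------------------------------------------------
# panel config I/O (YAML)


def _cell_to_dict(c: ExpectedOutcome) -> dict[str, Any]:
    d: dict[str, Any] = {}
    for k in ("product", "cut", "product_length", "fragments"):
        v = getattr(c, k)
        if v != ANY:
            d[k] = list(v) if isinstance(v, tuple) else v
    return d


def _cell_from_dict(d: dict[str, Any]) -> ExpectedOutcome:
    cell = ExpectedOutcome()
    if "product" in d:
        cell.product = d["product"]
    if "cut" in d:
        cell.cut = d["cut"]
    if "product_length" in d:
        cell.product_length = d["product_length"]
    if "fragments" in d and d["fragments"] != ANY:
        cell.fragments = tuple(d["fragments"])
    return cell


def save_panel(panel: MarkerPanel, path: str | Path) -> None:
    """Serialize a panel to YAML (primers, markers, profiles, model)."""
    doc: dict[str, Any] = {
        "model": {
            "max_mismatches": panel.model.max_mismatches,
            "clamp_length": panel.model.clamp_length,
            "min_product": panel.model.min_product,
            "max_product": panel.model.max_product,
        },
        "gel_resolution": {
            "floor_bp": panel.gel_resolution.floor_bp,
            "fraction": panel.gel_resolution.fraction,
        },
        "primers": {},
        "markers": [],
        "profiles": {},
    }
    primers: dict[str, str] = {}

    def reg(p: Primer) -> str:
        primers[p.name] = p.sequence
        return p.name

    for m in panel.markers:
        entry: dict[str, Any] = {
            "name": m.name,
            "type": m.marker_type,
            "fwd": reg(m.fwd),
            "rev": reg(m.rev),
        }
        if m.enzyme:
            entry["enzyme"] = m.enzyme
        if m.outer_pair:
            entry["outer"] = [reg(m.outer_pair[0]), reg(m.outer_pair[1])]
        doc["markers"].append(entry)
    doc["primers"] = primers
    for allele, row in panel.profile_table.items():
        doc["profiles"][allele] = {
            name: _cell_to_dict(cell) for name, cell in row.items()
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_panel(
    path: str | Path,
    enzyme_library: Sequence[RestrictionEnzyme] | None = None,
) -> MarkerPanel:
    """Load a YAML panel config and validate its structure."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "markers" not in doc or "profiles" not in doc:
        raise PanelError(f"{path}: not a panel config (need markers + profiles)")
    primers = {
        name: Primer(name=name, sequence=seq)
        for name, seq in (doc.get("primers") or {}).items()
    }

    def prim(name: str) -> Primer:
        if name not in primers:
            raise PanelError(f"{path}: marker references unknown primer {name!r}")
        return primers[name]

    markers = []
    for entry in doc["markers"]:
        outer = None
        if entry.get("outer"):
            outer = (prim(entry["outer"][0]), prim(entry["outer"][1]))
        markers.append(
            MarkerDefinition(
                name=entry["name"],
                marker_type=entry["type"],
                fwd=prim(entry["fwd"]),
                rev=prim(entry["rev"]),
                enzyme=entry.get("enzyme"),
                outer_pair=outer,
            )
        )
    profiles = {
        allele: {name: _cell_from_dict(d) for name, d in row.items()}
        for allele, row in doc["profiles"].items()
    }
    model_d = doc.get("model") or {}
    gel_d = doc.get("gel_resolution") or {}
    panel = MarkerPanel(
        markers=markers,
        profile_table=profiles,
        model=BindingModel(
            max_mismatches=model_d.get("max_mismatches", 1),
            clamp_length=model_d.get("clamp_length", 3),
            min_product=model_d.get("min_product", 50),
            max_product=model_d.get("max_product", 2000),
        ),
        gel_resolution=GelResolution(
            floor_bp=gel_d.get("floor_bp", 10),
            fraction=gel_d.get("fraction", 0.05),
        ),
        enzyme_library=list(enzyme_library)
        if enzyme_library is not None
        else default_enzyme_library(),
    )
    return panel
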