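"""Built-in ³¹P metabolite shift/coupling registry and basis-signal selection.

The registry is a typed, compiled-in transcription of the phantom measurement
table this package is built around: for each metabolite, the multiplet
structure of every ³¹P signal, its scalar coupling constant, and up to five
chemical-shift variants:

``ph70`` / ``ph75``
    phantom values measured at pH 7.0 and pH 7.5 (37 °C, PCr referenced to
    0 ppm as internal standard),
``invivo``
    a representative in vivo position (absent or qualitative for some rows),
``deelchand``
    the literature basis value the study compared against,
``basisp``
    the shift actually used in the fitting basis.  A signal belongs to the
    default fitting basis exactly when this variant is present; both ADP
    resonances are deliberately excluded because they are fully overlapped
    by the much stronger α/γ-ATP signals.

The default basis holds 20 signals drawn from 17 compounds (ATP contributes
three independent signals, UDPG and 2,3-DPG two each; MP and GPE are
literature-only singletons without phantom data).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

from .errors import MissingShiftError, UnknownMetaboliteError, ValidationError

__all__ = [
    "Multiplicity",
    "CouplingPartner",
    "MultipletComponent",
    "MetaboliteEntry",
    "Registry",
    "SHIFT_VARIANTS",
    "load_registry",
    "basis_signals",
    "shift_variant",
]

SHIFT_VARIANTS = ("ph70", "ph75", "invivo", "basisp", "deelchand")


class Multiplicity(str, Enum):
    SINGLET = "s"
    DOUBLET = "d"
    TRIPLET = "t"

    @property
    def n_lines(self) -> int:
        return {"s": 1, "d": 2, "t": 3}[self.value]


class CouplingPartner(str, Enum):
    PROTON = "proton"
    PHOSPHORUS = "phosphorus"
    NONE = "none"


@dataclass(frozen=True)
class MultipletComponent:
    """One ³¹P signal of a metabolite (a metabolite may carry several)."""

    label: str
    multiplicity: Multiplicity
    j_coupling: float | None = None          # Hz; None for singlets
    coupling_partner: CouplingPartner = CouplingPartner.NONE
    shift_ph70: float | None = None          # ppm
    shift_ph75: float | None = None
    shift_invivo: float | None = None        # representative numeric value
    invivo_text: str | None = None           # qualitative annotation as printed
    shift_deelchand: float | None = None
    shift_basisp: float | None = None        # present <=> signal enters the basis
    note: str | None = None

    def shift(self, variant: str) -> float:
        """Return the stored shift for ``variant`` (ppm), never a substitute."""
        if variant not in SHIFT_VARIANTS:
            raise ValidationError(
                f"unknown shift variant '{variant}'; expected one of {SHIFT_VARIANTS}"
            )
        value = getattr(self, f"shift_{variant}")
        if value is None:
            extra = f" ({self.invivo_text})" if variant == "invivo" and self.invivo_text else ""
            raise MissingShiftError(
                f"signal '{self.label}' has no tabulated shift for variant '{variant}'{extra}"
            )
        return float(value)

    def n_lines(self, decoupled: bool) -> int:
        """Number of resolved lines with/without ¹H decoupling.

        ¹H decoupling collapses proton-coupled multiplets to singlets and has
        no effect on P–P coupled multiplets.
        """
        if self.multiplicity is Multiplicity.SINGLET:
            return 1
        if decoupled and self.coupling_partner is CouplingPartner.PROTON:
            return 1
        return self.multiplicity.n_lines

    @property
    def in_basis(self) -> bool:
        return self.shift_basisp is not None


@dataclass(frozen=True)
class MetaboliteEntry:
    name: str
    abbrev: str
    components: tuple[MultipletComponent, ...]
    phantom_concentration: float | None = None  # mM; None for literature-only rows
    notes: tuple[str, ...] = ()

    @property
    def literature_only(self) -> bool:
        return "literature-only" in self.notes


@dataclass(frozen=True)
class Registry:
    entries: Mapping[str, MetaboliteEntry]
    version: str = "1.0"

    def __getitem__(self, abbrev: str) -> MetaboliteEntry:
        try:
            return self.entries[abbrev]
        except KeyError:
            raise UnknownMetaboliteError(
                f"unknown metabolite '{abbrev}'; known: {', '.join(self.entries)}"
            ) from None

    def __iter__(self):
        return iter(self.entries.values())

    def component(self, label: str) -> tuple[MetaboliteEntry, MultipletComponent]:
        for entry in self:
            for comp in entry.components:
                if comp.label == label:
                    return entry, comp
        raise UnknownMetaboliteError(f"unknown signal label '{label}'")

    @property
    def n_basis_signals(self) -> int:
        return sum(c.in_basis for e in self for c in e.components)

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "format": "phosfit-registry",
            "schema_version": 1,
            "version": self.version,
            "entries": [
                {
                    "name": e.name,
                    "abbrev": e.abbrev,
                    "phantom_concentration": e.phantom_concentration,
                    "notes": list(e.notes),
                    "components": [
                        {
                            "label": c.label,
                            "multiplicity": c.multiplicity.value,
                            "j_coupling": c.j_coupling,
                            "coupling_partner": c.coupling_partner.value,
                            "shift_ph70": c.shift_ph70,
                            "shift_ph75": c.shift_ph75,
                            "shift_invivo": c.shift_invivo,
                            "invivo_text": c.invivo_text,
                            "shift_deelchand": c.shift_deelchand,
                            "shift_basisp": c.shift_basisp,
                            "note": c.note,
                        }
                        for c in e.components
                    ],
                }
                for e in self
            ],
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Registry":
        doc = json.loads(text)
        if doc.get("format") != "phosfit-registry":
            raise ValidationError("not a phosfit registry document")
        entries = {}
        for e in doc["entries"]:
            comps = tuple(
                MultipletComponent(
                    label=c["label"],
                    multiplicity=Multiplicity(c["multiplicity"]),
                    j_coupling=c["j_coupling"],
                    coupling_partner=CouplingPartner(c["coupling_partner"]),
                    shift_ph70=c["shift_ph70"],
                    shift_ph75=c["shift_ph75"],
                    shift_invivo=c["shift_invivo"],
                    invivo_text=c["invivo_text"],
                    shift_deelchand=c["shift_deelchand"],
                    shift_basisp=c["shift_basisp"],
                    note=c["note"],
                )
                for c in e["components"]
            )
            entries[e["abbrev"]] = MetaboliteEntry(
                name=e["name"],
                abbrev=e["abbrev"],
                components=comps,
                phantom_concentration=e["phantom_concentration"],
                notes=tuple(e["notes"]),
            )
        return cls(entries=entries, version=doc["version"])

    _TABLE_COLUMNS = (
        "abbrev", "name", "phantom_concentration", "entry_notes",
        "label", "multiplicity", "j_coupling", "coupling_partner",
        "shift_ph70", "shift_ph75", "shift_invivo", "invivo_text",
        "shift_deelchand", "shift_basisp", "note",
    )

    def to_table(self) -> str:
        """Plain-text tab-delimited export; floats round-trip bit-exactly."""

        def cell(v) -> str:
            if v is None:
                return ""
            if isinstance(v, float):
                return repr(v)
            return str(v)

        lines = ["#phosfit-registry-table\tv1\t" + self.version,
                 "\t".join(self._TABLE_COLUMNS)]
        for e in self:
            for i, c in enumerate(e.components):
                row = [
                    e.abbrev, e.name,
                    cell(e.phantom_concentration) if i == 0 else "",
                    ";".join(e.notes) if i == 0 else "",
                    c.label, c.multiplicity.value, cell(c.j_coupling),
                    c.coupling_partner.value,
                    cell(c.shift_ph70), cell(c.shift_ph75), cell(c.shift_invivo),
                    c.invivo_text or "", cell(c.shift_deelchand),
                    cell(c.shift_basisp), c.note or "",
                ]
                lines.append("\t".join(row))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_table(cls, text: str) -> "Registry":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        header = lines[0].split("\t")
        if not header or header[0] != "#phosfit-registry-table":
            raise ValidationError("not a phosfit registry table")
        version = header[2] if len(header) > 2 else "1.0"
        cols = lines[1].split("\t")
        if tuple(cols) != cls._TABLE_COLUMNS:
            raise ValidationError("registry table column mismatch")

        def num(s: str) -> float | None:
            return float(s) if s else None

        grouped: dict[str, dict] = {}
        order: list[str] = []
        for ln in lines[2:]:
            row = dict(zip(cls._TABLE_COLUMNS, ln.split("\t")))
            ab = row["abbrev"]
            if ab not in grouped:
                grouped[ab] = {
                    "name": row["name"],
                    "phantom_concentration": num(row["phantom_concentration"]),
                    "notes": tuple(n for n in row["entry_notes"].split(";") if n),
                    "components": [],
                }
                order.append(ab)
            grouped[ab]["components"].append(
                MultipletComponent(
                    label=row["label"],
                    multiplicity=Multiplicity(row["multiplicity"]),
                    j_coupling=num(row["j_coupling"]),
                    coupling_partner=CouplingPartner(row["coupling_partner"]),
                    shift_ph70=num(row["shift_ph70"]),
                    shift_ph75=num(row["shift_ph75"]),
                    shift_invivo=num(row["shift_invivo"]),
                    invivo_text=row["invivo_text"] or None,
                    shift_deelchand=num(row["shift_deelchand"]),
                    shift_basisp=num(row["shift_basisp"]),
                    note=row["note"] or None,
                )
            )
        entries = {
            ab: MetaboliteEntry(
                name=g["name"], abbrev=ab, components=tuple(g["components"]),
                phantom_concentration=g["phantom_concentration"], notes=g["notes"],
            )
            for ab, g in ((ab, grouped[ab]) for ab in order)
        }
        return cls(entries=entries, version=version)


# ---------------------------------------------------------------------------
# compiled-in data
# ---------------------------------------------------------------------------

_S = Multiplicity.SINGLET
_D = Multiplicity.DOUBLET
_T = Multiplicity.TRIPLET
_H = CouplingPartner.PROTON
_P = CouplingPartner.PHOSPHORUS
_N = CouplingPartner.NONE


def _c(label, mult, j, partner, ph70, ph75, invivo, deel, basisp,
       invivo_text=None, note=None):
    return MultipletComponent(
        label=label, multiplicity=mult, j_coupling=j, coupling_partner=partner,
        shift_ph70=ph70, shift_ph75=ph75, shift_invivo=invivo,
        invivo_text=invivo_text, shift_deelchand=deel, shift_basisp=basisp,
        note=note,
    )


def _build_entries() -> dict[str, MetaboliteEntry]:
    entries = [
        MetaboliteEntry(
            "phosphocreatine", "PCr",
            (_c("PCr", _S, None, _N, 0.0, 0.0, 0.0, 0.0, 0.0),),
            phantom_concentration=5.0,
            notes=("internal standard",),
        ),
        MetaboliteEntry(
            "inorganic phosphate", "Pi",
            (_c("Pi", _S, None, _N, 4.78, 5.27, 5.0, 4.84, 4.78,
                invivo_text="~5"),),
            phantom_concentration=40.0,
            notes=("buffer component of every phantom",),
        ),
        MetaboliteEntry(
            "adenosine triphosphate", "ATP",
            (
                _c("aATP", _D, 19.5, _P, -7.98, -7.94, -7.5, -7.56, -7.53,
                   invivo_text="~7-8"),
                _c("bATP", _T, 20.0, _P, -18.80, -18.58, -16.0, -16.18, -16.18,
                   invivo_text="~16"),
                _c("gATP", _D, 19.0, _P, -4.18, -3.37, -3.5, -2.53, -2.7,
                   invivo_text="~3-4"),
            ),
            phantom_concentration=10.0,
            notes=("basis shifts adjusted toward in vivo positions",),
        ),
        MetaboliteEntry(
            "adenosine diphosphate", "ADP",
            (
                _c("aADP", _D, 19.0, _P, -7.28, -7.32, None, None, None),
                _c("bADP", _D, 19.5, _P, -3.50, -3.20, None, None, None),
            ),
            phantom_concentration=10.0,
            notes=("excluded from basis: overlapped by alpha/gamma-ATP",),
        ),
        MetaboliteEntry(
            "phosphoethanolamine", "PE",
            (_c("PE", _T, 7.0, _H, 6.74, 6.85, 6.78, 6.77, 6.77),),
            phantom_concentration=10.0,
        ),
        MetaboliteEntry(
            "phosphocholine", "PC",
            (_c("PC", _T, 6.0, _H, 6.19, 6.35, 5.9, 6.23, 6.23),),
            phantom_concentration=10.0,
        ),
        MetaboliteEntry(
            "glucose-1-phosphate", "G1P",
            (_c("G1P", _D, 7.5, _H, 4.99, None, None, None, 4.99,
                invivo_text="overlaps PME",
                note="pH-7.5 resonance coincides with Pi (5.20)"),),
            phantom_concentration=10.0,
        ),
        MetaboliteEntry(
            "glucose-6-phosphate", "G6P",
            (_c("G6P", _T, 6.1, _H, 7.03, 7.30, 7.15, None, 7.03,
                invivo_text="7.1-7.2"),),
            phantom_concentration=10.0,
        ),
        MetaboliteEntry(
            "phosphoenolpyruvate", "PEP",
            (_c("PEP", _S, None, _N, 2.00, 2.27, 2.06, None, 2.0),),
            phantom_concentration=10.0,
        ),
        MetaboliteEntry(
            "phosphatidylcholine", "PtdC",
            (_c("PtdC", _T, 6.0, _H, 2.14, 2.13, 2.06, None, 2.14,
                note="pH-7.0 slot measured at pH 7.21; J not tabulated, "
                     "nominal choline-like 6.0 Hz assigned"),),
            phantom_concentration=10.0,
            notes=("solvent: 40% ethanol with Triton-100 surfactant",),
        ),
        MetaboliteEntry(
            "glycerophosphocholine", "GPC",
            (_c("GPC", _T, 5.5, _H, 2.97, 2.96, 2.76, 2.94, 2.97),),
            phantom_concentration=10.0,
        ),
        MetaboliteEntry(
            "2,3-diphosphoglycerate", "DPG23",
            (
                _c("DPG23_2", _D, 6.0, _H, 4.09, 4.6, 5.5, 5.23, 4.05,
                   note="2-phosphate; in-blood position shifted by Hb binding"),
                _c("DPG23_3", _T, 9.5, _H, 5.338, 5.84, 6.3, 5.71, 5.32,
                   note="3-phosphate"),
            ),
            phantom_concentration=2.0,
            notes=("reduced-concentration phantom (buffer 10 mM)",),
        ),
        MetaboliteEntry(
            "nicotinamide adenine dinucleotide (reduced)", "NADH",
            (_c("NADH", _S, None, _N, -8.16, -8.16, -8.1, -8.13, -8.13,
                invivo_text="~8.1"),),
            phantom_concentration=10.0,
        ),
        MetaboliteEntry(
            "nicotinamide adenine dinucleotide (oxidized)", "NADplus",
            (_c("NAD+", _D, 6.0, _P, -8.32, -8.32, -8.3, -8.31, -8.31,
                invivo_text="~8.3",
                note="modeled as resolved P-P doublet; appears as an "
                     "unresolved singlet without decoupling in vivo"),),
            phantom_concentration=10.0,
        ),
        MetaboliteEntry(
            "uridine diphosphoglucose", "UDPG",
            (
                _c("UDPG_rib", _D, 10.0, _P, -8.11, -8.11, -8.1, None, -7.98,
                   note="phosphorus attached to the ribose part"),
                _c("UDPG_glc", _D, 10.0, _P, -9.78, -9.78, -9.8, None, -9.78,
                   note="phosphorus attached to the glucose part"),
            ),
            phantom_concentration=2.0,
            notes=("reduced-concentration phantom (buffer 10 mM)",),
        ),
        MetaboliteEntry(
            "membrane phospholipids", "MP",
            (_c("MP", _S, None, _N, None, None, None, 2.3, 2.3,
                note="broad background resonance"),),
            phantom_concentration=None,
            notes=("literature-only",),
        ),
        MetaboliteEntry(
            "glycerophosphoethanolamine", "GPE",
            (_c("GPE", _S, None, _N, None, None, None, 3.49, 3.49),),
            phantom_concentration=None,
            notes=("literature-only",),
        ),
    ]
    return {e.abbrev: e for e in entries}


def _validate(reg: Registry) -> None:
    assert len(reg.entries) == 17
    for entry in reg:
        for comp in entry.components:
            if comp.multiplicity is not Multiplicity.SINGLET:
                if not (comp.j_coupling and comp.j_coupling > 0):
                    raise ValidationError(f"{comp.label}: multiplet without J")
                if comp.coupling_partner is CouplingPartner.NONE:
                    raise ValidationError(f"{comp.label}: multiplet without partner")
    if any(c.in_basis for c in reg["ADP"].components):
        raise ValidationError("ADP signals must not be basis-eligible")
    pcr = reg["PCr"].components[0]
    if not (pcr.shift_ph70 == 0.0 == pcr.shift_ph75):
        raise ValidationError("PCr must reference 0 ppm at both pH values")
    expected_n = {"ATP": 3, "ADP": 2, "DPG23": 2, "UDPG": 2}
    for entry in reg:
        if len(entry.components) != expected_n.get(entry.abbrev, 1):
            raise ValidationError(f"{entry.abbrev}: unexpected component count")


def load_registry() -> Registry:
    """Return the compiled-in registry (validated)."""
    reg = Registry(entries=_build_entries(), version="1.0")
    _validate(reg)
    return reg


def shift_variant(component: MultipletComponent, variant: str) -> float:
    """Stored chemical shift of ``component`` for ``variant`` (ppm)."""
    return component.shift(variant)


def _resolve(reg: Registry, names: Iterable[str]) -> set[str]:
    """Expand entry abbrevs / component labels into a set of component labels."""
    labels: set[str] = set()
    for name in names:
        if name in reg.entries:
            labels.update(c.label for c in reg.entries[name].components)
        else:
            _, comp = reg.component(name)  # raises UnknownMetaboliteError
            labels.add(comp.label)
    return labels


def basis_signals(
    reg: Registry,
    include: Iterable[str] | None = None,
    exclude: Iterable[str] | None = None,
) -> list[tuple[MetaboliteEntry, MultipletComponent]]:
    """Ordered basis-eligible signals (descending ppm, ties by label).

    ``include``/``exclude`` accept entry abbrevs (expanding to all of that
    entry's signals) or individual signal labels; unknown names raise
    :class:`UnknownMetaboliteError`.
    """
    inc = _resolve(reg, include) if include is not None else None
    exc = _resolve(reg, exclude) if exclude is not None else set()
    out = []
    for entry in reg:
        for comp in entry.components:
            if not comp.in_basis:
                continue
            if inc is not None and comp.label not in inc:
                continue
            if comp.label in exc:
                continue
            out.append((entry, comp))
    out.sort(key=lambda ec: (-ec[1].shift_basisp, ec[1].label))
    return out
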