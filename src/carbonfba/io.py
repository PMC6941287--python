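"""Readers and writers: reaction-equation strings, SBML, delimited tables.

SBML is written as Level 3 Version 1 with the flux-bounds constructs of the
fbc (version 2) package; on reading, both that dialect and the legacy
kinetic-law LOWER_BOUND/UPPER_BOUND parameters are accepted.  Networks that
encode exchanges with explicit boundary species are normalized on import to
the single-sided-column convention used internally.
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import libsbml
import numpy as np
import pandas as pd

from .core import (
    KNOWN_ROLES,
    Compartment,
    Metabolite,
    Reaction,
    ReactionKind,
    StoichiometricNetwork,
    validate_network,
)
from .scenarios import ScenarioRow, ScenarioTable

__all__ = [
    "EquationParseError",
    "SchemaError",
    "ReactionTableRow",
    "parse_reaction_equation",
    "format_reaction_equation",
    "read_sbml",
    "write_sbml",
    "read_reaction_table",
    "network_from_rows",
    "write_scenario_table",
    "read_scenario_table",
    "DEFAULT_COMPARTMENT_MAP",
]

Source = Union[str, Path, _io.IOBase]


class EquationParseError(ValueError):
    """Reaction-equation syntax error, carrying the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at character {position})")
        self.position = position


class SchemaError(ValueError):
    """A delimited file lacks mandatory columns."""


# ---------------------------------------------------------------------------
# reaction equation grammar

_ARROWS = [
    ("<=>", True), ("<->", True), ("⇌", True),
    ("-->", False), ("->", False), ("=>", False), ("→", False),
]
_COEF_RE = re.compile(r"^(\d+(?:\.\d+)?(?:[eE][+-]?\d+)?|\.\d+)$")
_EMPTY_SIDE_TOKENS = {"", "∅", "0", "nothing"}


def _find_arrow(text: str) -> tuple[int, str, bool]:
    best = None
    for arrow, rev in _ARROWS:
        pos = text.find(arrow)
        if pos >= 0 and (best is None or pos < best[0]):
            best = (pos, arrow, rev)
            break  # arrow list is ordered longest-first per prefix family
    if best is None:
        raise EquationParseError("no reaction arrow (->, <=>, ...) found", len(text))
    return best


def _parse_side(text: str, offset: int, sign: float, stoich: dict[str, float]) -> None:
    if text.strip() in _EMPTY_SIDE_TOKENS:
        return
    pos = 0
    for chunk in re.split(r"(\s\+\s|^\+\s|\s\+$)", text):
        if re.fullmatch(r"\s\+\s|^\+\s|\s\+$", chunk or ""):
            pos += len(chunk)
            continue
        term = chunk
        term_start = offset + pos + (len(term) - len(term.lstrip()))
        stripped = term.strip()
        pos += len(chunk)
        if not stripped:
            raise EquationParseError("empty term", term_start)
        parts = stripped.split(None, 1)
        if len(parts) == 2:
            coef_txt, species = parts
            if not _COEF_RE.match(coef_txt):
                raise EquationParseError(
                    f"non-numeric coefficient {coef_txt!r}", term_start
                )
            coef = float(coef_txt)
        else:
            coef, species = 1.0, stripped
        if coef == 0:
            raise EquationParseError("zero coefficient", term_start)
        stoich[species] = stoich.get(species, 0.0) + sign * coef
        if stoich[species] == 0.0:
            del stoich[species]


def parse_reaction_equation(text: str) -> tuple[dict[str, float], bool]:
    """Parse ``"glc[c] + 2 atp[c] -> g6p[c] + 2 adp[c]"`` style equations.

    Returns the signed stoichiometry (negative = consumed) and the
    reversibility flag; ``<=>``/``<->`` arrows mean reversible.  Terms are
    '+'-separated with an optional leading numeric coefficient (default 1)
    and may carry compartment tags in brackets.  Raises
    :class:`EquationParseError` with the character position on bad input.
    """
    if not text or not text.strip():
        raise EquationParseError("empty equation", 0)
    pos, arrow, reversible = _find_arrow(text)
    lhs, rhs = text[:pos], text[pos + len(arrow):]
    stoich: dict[str, float] = {}
    _parse_side(lhs, 0, -1.0, stoich)
    _parse_side(rhs, pos + len(arrow), +1.0, stoich)
    if not stoich:
        raise EquationParseError("equation has no species", 0)
    return stoich, reversible


def _coef_text(c: float) -> str:
    return format(c, "g")


def format_reaction_equation(stoichiometry: Mapping[str, float], reversible: bool) -> str:
    """Canonical text form; inverse of :func:`parse_reaction_equation`."""
    lhs = [(m, -c) for m, c in stoichiometry.items() if c < 0]
    rhs = [(m, c) for m, c in stoichiometry.items() if c > 0]

    def side(terms):
        return " + ".join(
            f"{_coef_text(c)} {m}" if c != 1 else m for m, c in terms
        )

    arrow = "<=>" if reversible else "->"
    return f"{side(lhs)} {arrow} {side(rhs)}".strip()


# ---------------------------------------------------------------------------
# reaction table (supplementary-style delimited text)


@dataclass(frozen=True)
class ReactionTableRow:
    reaction_id: str
    equation_text: str
    name: str = ""
    ec_number: Optional[str] = None
    kegg_id: Optional[str] = None
    compartment_hint: Optional[str] = None
    reversible: Optional[bool] = None


_ID_COLS = ("reaction_id", "id", "reaction", "abbreviation", "rid")
_EQ_COLS = ("equation", "reaction_equation", "formula", "equation_text")
_EC_COLS = ("ec_number", "ec", "ec number")
_KEGG_COLS = ("kegg_id", "kegg", "kegg id")
_NAME_COLS = ("name", "reaction_name", "description")
_COMP_COLS = ("compartment", "compartment_hint", "localization")


def _pick(columns: Sequence[str], candidates: Sequence[str]) -> Optional[str]:
    lowered = {c.lower().strip(): c for c in columns}
    for cand in candidates:
        if cand in lowered:
            return lowered[cand]
    return None


def read_reaction_table(source: Source, delimiter: Optional[str] = None) -> list[ReactionTableRow]:
    """Read a delimited reaction list (comma/tab/semicolon auto-detected).

    Mandatory columns: a reaction id and an equation (several common
    spellings accepted); EC/KEGG/name/compartment are optional and missing
    cells become ``None``, never empty strings.
    """
    df = pd.read_csv(
        source,
        sep=delimiter,
        engine="python" if delimiter is None else "c",
        dtype=str,
        keep_default_na=False,
    )
    id_col = _pick(df.columns, _ID_COLS)
    eq_col = _pick(df.columns, _EQ_COLS)
    missing = [label for label, col in (("id", id_col), ("equation", eq_col)) if col is None]
    if missing:
        raise SchemaError(
            f"reaction table lacks mandatory column(s): {', '.join(missing)}; "
            f"found columns: {list(df.columns)}"
        )
    ec_col = _pick(df.columns, _EC_COLS)
    kegg_col = _pick(df.columns, _KEGG_COLS)
    name_col = _pick(df.columns, _NAME_COLS)
    comp_col = _pick(df.columns, _COMP_COLS)

    def cell(row, col):
        if col is None:
            return None
        v = str(row[col]).strip()
        return v or None

    rows = []
    for _, r in df.iterrows():
        rows.append(
            ReactionTableRow(
                reaction_id=str(r[id_col]).strip(),
                equation_text=str(r[eq_col]).strip(),
                name=cell(r, name_col) or "",
                ec_number=cell(r, ec_col),
                kegg_id=cell(r, kegg_col),
                compartment_hint=cell(r, comp_col),
            )
        )
    return rows


DEFAULT_COMPARTMENT_MAP: dict[str, Compartment] = {
    "c": Compartment.CYTOSOL, "cyt": Compartment.CYTOSOL, "cytosol": Compartment.CYTOSOL,
    "h": Compartment.CHLOROPLAST, "chl": Compartment.CHLOROPLAST,
    "plastid": Compartment.CHLOROPLAST, "chloroplast": Compartment.CHLOROPLAST,
    "m": Compartment.MITOCHONDRION, "mit": Compartment.MITOCHONDRION,
    "mitochondrion": Compartment.MITOCHONDRION,
    "e": Compartment.EXTERNAL, "ext": Compartment.EXTERNAL,
    "b": Compartment.EXTERNAL, "boundary": Compartment.EXTERNAL,
    "external": Compartment.EXTERNAL,
}

_TAG_RE = re.compile(r"\[([^\[\]]+)\]\s*$")


def _species_compartment(
    species_id: str, comp_map: Mapping[str, Compartment]
) -> Compartment:
    m = _TAG_RE.search(species_id)
    if m:
        tag = m.group(1).lower()
        if tag in comp_map:
            return comp_map[tag]
    return Compartment.CYTOSOL


def network_from_rows(
    rows: Iterable[ReactionTableRow],
    compartment_map: Optional[Mapping[str, Compartment]] = None,
    named_roles: Optional[Mapping[str, str]] = None,
    name: str = "",
) -> StoichiometricNetwork:
    """Assemble a network from parsed table rows.

    Metabolite compartments come from bracket tags in species names
    (``dhap[h]`` -> chloroplast) through the compartment map; untagged
    species default to the cytosol.
    """
    comp_map = dict(DEFAULT_COMPARTMENT_MAP)
    comp_map.update(compartment_map or {})
    mets: dict[str, Metabolite] = {}
    rxns: list[Reaction] = []
    for row in rows:
        stoich, reversible = parse_reaction_equation(row.equation_text)
        if row.reversible is not None:
            reversible = row.reversible
        for sp in stoich:
            if sp not in mets:
                mets[sp] = Metabolite(sp, compartment=_species_compartment(sp, comp_map))
        rxns.append(
            Reaction(
                row.reaction_id,
                stoich,
                name=row.name,
                reversible=reversible,
                ec_number=row.ec_number,
                kegg_id=row.kegg_id,
            )
        )
    return StoichiometricNetwork(mets.values(), rxns, named_roles=named_roles, name=name)


# ---------------------------------------------------------------------------
# SBML

_SID_OK = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


def _encode_sid(raw: str, prefix: str) -> str:
    out = []
    for ch in raw:
        if ch.isalnum() or ch == "_":
            out.append(ch)
        else:
            out.append(f"__{ord(ch)}__")
    return prefix + "".join(out)


_DECODE_RE = re.compile(r"__(\d+)__")


def _decode_sid(sid: str, prefix: str) -> str:
    if sid.startswith(prefix):
        sid = sid[len(prefix):]
    return _DECODE_RE.sub(lambda m: chr(int(m.group(1))), sid)


def _notes_xml(fields: Mapping[str, str]) -> str:
    items = "".join(
        f"<p>{k}: {v}</p>" for k, v in fields.items() if v
    )
    return f'<body xmlns="http://www.w3.org/1999/xhtml">{items}</body>'


_NOTE_RE = re.compile(r"<p>\s*([A-Za-z0-9_ ]+?)\s*:\s*(.*?)\s*</p>", re.S)


def _parse_notes(node) -> dict[str, str]:
    if node is None or not node.isSetNotes():
        return {}
    txt = node.getNotesString()
    return {m.group(1): m.group(2) for m in _NOTE_RE.finditer(txt)}


def write_sbml(network: StoichiometricNetwork, sink: Optional[Source] = None) -> str:
    """Serialize a network to SBML L3V1 + fbc v2 with deterministic output.

    The network must validate without errors.  Bounds are written as fbc
    flux-bound parameters; annotations (EC, KEGG, reaction kind, named
    roles) go into notes so they round-trip exactly.  Returns the document
    text; if ``sink`` is given it is also written there.
    """
    report = validate_network(network)
    if report.has_errors():
        msgs = "; ".join(i.message for i in report.errors)
        raise ValueError(f"refusing to write invalid network: {msgs}")

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    model = doc.createModel()
    model.setId(_encode_sid(network.name or "model", "mdl_"))
    mplug = model.getPlugin("fbc")
    mplug.setStrict(False)

    model_notes = {}
    for role in KNOWN_ROLES:
        if role in network.named_roles:
            model_notes[f"ROLE {role}"] = network.named_roles[role]
    if model_notes:
        model.setNotes(_notes_xml(model_notes))

    used_comps: list[Compartment] = []
    for met in network.metabolites:
        if met.compartment not in used_comps:
            used_comps.append(met.compartment)
    for comp in used_comps:
        c = model.createCompartment()
        c.setId(network.compartment_ids.get(comp, comp.value))
        c.setName(comp.value)
        c.setConstant(True)

    for met in network.metabolites:
        s = model.createSpecies()
        s.setId(_encode_sid(met.id, "M_"))
        s.setName(met.name or met.id)
        s.setCompartment(network.compartment_ids.get(met.compartment, met.compartment.value))
        s.setConstant(False)
        s.setBoundaryCondition(False)
        s.setHasOnlySubstanceUnits(False)
        notes = {}
        if met.formula:
            notes["FORMULA"] = met.formula
        if notes:
            s.setNotes(_notes_xml(notes))

    for rxn in network.reactions:
        r = model.createReaction()
        rid = _encode_sid(rxn.id, "R_")
        r.setId(rid)
        r.setName(rxn.name or rxn.id)
        r.setReversible(rxn.reversible)
        r.setFast(False)
        for met_id, coef in rxn.stoichiometry.items():
            ref = r.createReactant() if coef < 0 else r.createProduct()
            ref.setSpecies(_encode_sid(met_id, "M_"))
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rplug = r.getPlugin("fbc")
        if rxn.has_bounds:
            for tag, value in (("lb", rxn.lower_bound), ("ub", rxn.upper_bound)):
                p = model.createParameter()
                p.setId(f"{rid}_{tag}")
                p.setValue(float(value))
                p.setConstant(True)
            rplug.setLowerFluxBound(f"{rid}_lb")
            rplug.setUpperFluxBound(f"{rid}_ub")
        notes = {"KIND": rxn.kind.value}
        if rxn.ec_number:
            notes["EC"] = rxn.ec_number
        if rxn.kegg_id:
            notes["KEGG"] = rxn.kegg_id
        r.setNotes(_notes_xml(notes))

    text = libsbml.writeSBMLToString(doc)
    if sink is not None:
        if isinstance(sink, (str, Path)):
            Path(sink).write_text(text)
        else:
            sink.write(text)
    return text


def _document_from_source(source: Source) -> libsbml.SBMLDocument:
    if isinstance(source, Path) or (
        isinstance(source, str) and not source.lstrip().startswith("<")
    ):
        doc = libsbml.readSBMLFromFile(str(source))
    elif isinstance(source, str):
        doc = libsbml.readSBMLFromString(source)
    else:
        doc = libsbml.readSBMLFromString(source.read())
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            raise IOError(f"malformed SBML: {err.getMessage()}")
    return doc


def read_sbml(
    source: Source,
    compartment_map: Optional[Mapping[str, Compartment]] = None,
) -> StoichiometricNetwork:
    """Read SBML (L2 or L3, with fbc or kinetic-law bounds) into a network.

    Compartment ids are mapped onto the four-valued compartment enum via
    :data:`DEFAULT_COMPARTMENT_MAP`, overridable through
    ``compartment_map``; an unmapped compartment id raises a validation
    error naming it.  Boundary-condition species are normalized away so
    exchange reactions become single-sided columns.
    """
    comp_map_raw = dict(DEFAULT_COMPARTMENT_MAP)
    comp_map_raw.update(compartment_map or {})
    comp_map = {k.lower(): v for k, v in comp_map_raw.items()}
    doc = _document_from_source(source)
    model = doc.getModel()
    if model is None:
        raise IOError("SBML document contains no model")

    compartments: dict[str, Compartment] = {}
    compartment_ids: dict[Compartment, str] = {}
    for i in range(model.getNumCompartments()):
        comp = model.getCompartment(i)
        cid = comp.getId()
        key = cid.lower()
        name_key = (comp.getName() or "").lower()
        if key in comp_map:
            mapped = comp_map[key]
        elif name_key in comp_map:
            mapped = comp_map[name_key]
        else:
            raise ValueError(
                f"unknown compartment id {cid!r}: supply a compartment_map entry"
            )
        compartments[cid] = mapped
        compartment_ids.setdefault(mapped, cid)

    mets: list[Metabolite] = []
    boundary: set[str] = set()
    sid_to_id: dict[str, str] = {}
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        sid = sp.getId()
        if sp.getCompartment() not in compartments:
            raise ValueError(
                f"species {sid!r} references missing compartment {sp.getCompartment()!r}"
            )
        raw_id = _decode_sid(sid, "M_")
        sid_to_id[sid] = raw_id
        if sp.isSetBoundaryCondition() and sp.getBoundaryCondition():
            boundary.add(sid)
            continue
        notes = _parse_notes(sp)
        mets.append(
            Metabolite(
                raw_id,
                name=sp.getName() or raw_id,
                compartment=compartments[sp.getCompartment()],
                formula=notes.get("FORMULA"),
            )
        )

    def _bound_params(r) -> tuple[Optional[float], Optional[float]]:
        rplug = r.getPlugin("fbc")
        lb = ub = None
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                p = model.getParameter(rplug.getLowerFluxBound())
                lb = p.getValue() if p is not None else None
            if rplug.isSetUpperFluxBound():
                p = model.getParameter(rplug.getUpperFluxBound())
                ub = p.getValue() if p is not None else None
        kl = r.getKineticLaw()
        if kl is not None:
            for j in range(kl.getNumParameters()):
                p = kl.getParameter(j)
                if p.getId() == "LOWER_BOUND" and lb is None:
                    lb = p.getValue()
                elif p.getId() == "UPPER_BOUND" and ub is None:
                    ub = p.getValue()
        return lb, ub

    rxns: list[Reaction] = []
    for i in range(model.getNumReactions()):
        r = model.getReaction(i)
        stoich: dict[str, float] = {}
        for ref, sign in [
            (r.getReactant(j), -1.0) for j in range(r.getNumReactants())
        ] + [
            (r.getProduct(j), +1.0) for j in range(r.getNumProducts())
        ]:
            sid = ref.getSpecies()
            if sid in boundary:
                continue  # normalize the explicit-boundary dialect
            if sid not in sid_to_id:
                raise ValueError(f"reaction {r.getId()!r} references unknown species {sid!r}")
            met_id = sid_to_id[sid]
            coef = ref.getStoichiometry()
            stoich[met_id] = stoich.get(met_id, 0.0) + sign * coef
        stoich = {k: v for k, v in stoich.items() if v != 0.0}
        if not stoich:
            continue  # pure boundary<->boundary reaction carries no balance
        notes = _parse_notes(r)
        lb, ub = _bound_params(r)
        reversible = r.getReversible() if r.isSetReversible() else True
        kind = notes.get("KIND", ReactionKind.INTERNAL.value)
        try:
            kind_enum = ReactionKind(kind)
        except ValueError:
            kind_enum = ReactionKind.INTERNAL
        if not reversible and lb is not None and lb < 0:
            reversible = True  # trust bounds over the flag
        rxns.append(
            Reaction(
                _decode_sid(r.getId(), "R_"),
                stoich,
                name=r.getName() or "",
                reversible=reversible,
                lower_bound=lb,
                upper_bound=ub,
                ec_number=notes.get("EC"),
                kegg_id=notes.get("KEGG"),
                kind=kind_enum,
            )
        )

    model_notes = _parse_notes(model)
    named_roles = {}
    for key, value in model_notes.items():
        if key.startswith("ROLE "):
            named_roles[key[len("ROLE "):]] = value
    named_roles = {k: v for k, v in named_roles.items()
                   if any(v == r.id for r in rxns)}

    return StoichiometricNetwork(
        mets,
        rxns,
        named_roles=named_roles,
        name=_decode_sid(model.getId(), "mdl_") if model.isSetId() else "",
        compartment_ids=compartment_ids,
    )


# ---------------------------------------------------------------------------
# scenario tables

_TABLE_ROWS = (
    "Light (Ex01)",
    "Nutrients (Ex06, NO3-)",
    "Objective function",
    "Calc. growth rate in 1/h",
    "Calc. beta-carotene production in mmol/(g dw.h)",
    "Status",
)
_NUMERIC_ROWS = {
    "Light (Ex01)", "Nutrients (Ex06, NO3-)",
    "Calc. growth rate in 1/h",
    "Calc. beta-carotene production in mmol/(g dw.h)",
}


def write_scenario_table(table: ScenarioTable, sink: Optional[Source] = None,
                         sep: str = "\t") -> str:
    """Delimited text, columns = scenarios, rows = inputs then outputs.

    Numbers are printed to 4 decimal places, the precision of the
    reference tables.
    """
    df = table.to_frame()
    out = df.copy()
    for row in _NUMERIC_ROWS:
        out.loc[row] = [
            "" if (isinstance(v, float) and np.isnan(v)) else f"{float(v):.4f}"
            for v in df.loc[row]
        ]
    text = out.to_csv(sep=sep, index_label="Scenario")
    if sink is not None:
        if isinstance(sink, (str, Path)):
            Path(sink).write_text(text)
        else:
            sink.write(text)
    return text


def read_scenario_table(source: Source, sep: str = "\t") -> ScenarioTable:
    """Inverse of :func:`write_scenario_table` (to 4-decimal precision)."""
    df = pd.read_csv(source, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    table = ScenarioTable()
    for label in df.columns:
        col = df[label]

        def num(row):
            v = str(col[row]).strip()
            return float(v) if v else float("nan")

        table.rows.append(
            ScenarioRow(
                label=label,
                light_flux=num("Light (Ex01)"),
                nitrate_flux=num("Nutrients (Ex06, NO3-)"),
                objective=str(col["Objective function"]),
                status=str(col["Status"]),
                growth_rate=num("Calc. growth rate in 1/h"),
                carotene_flux=num("Calc. beta-carotene production in mmol/(g dw.h)"),
            )
        )
    return table
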