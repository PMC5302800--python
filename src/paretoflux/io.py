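"""Readers and writers for strain models, community models and thermo tables.

Three formats are supported:

* **tabular** -- one TSV per strain with ``[METABOLITES]`` and ``[REACTIONS]``
  sections; reactions are written as formula strings
  (``"1 A + 2 B -> 1 C"``).  This dialect exists because curated community
  models usually travel as spreadsheets rather than SBML.
* **SBML** (level 3 + FBC bounds/objective), read and written through
  cobrapy/libsbml.
* **community JSON** -- a single document holding strains, pool spec and
  couplings, with exact float round-tripping.

Bounds absent from a file default to [-1000, 1000] for reversible and
[0, 1000] for irreversible reactions.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

from .community import CommunityModel, LinearCoupling, PoolSpec
from .core import DEFAULT_BOUND, Metabolite, Reaction, StrainModel, ThermoTable
from .errors import ParseError, ValidationError

# ---------------------------------------------------------------------------
# formula strings

_TERM_RE = re.compile(r"^\s*(?:(\d+\.?\d*(?:[eE][-+]?\d+)?)\s+)?(\S.*?)\s*$")


def parse_formula(formula: str) -> dict[str, float]:
    """Parse ``"a A + b B -> c C"`` into a signed stoichiometry map."""
    for arrow in ("<->", "<=>", "->", "=>"):
        if arrow in formula:
            lhs, rhs = formula.split(arrow, 1)
            break
    else:
        raise ParseError(f"no reaction arrow in formula {formula!r}")
    stoich: dict[str, float] = {}

    def add(side: str, sign: float):
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            m = _TERM_RE.match(term)
            if not m or not m.group(2):
                raise ParseError(f"cannot parse term {term!r} in {formula!r}")
            coef = float(m.group(1)) if m.group(1) else 1.0
            met = m.group(2)
            stoich[met] = stoich.get(met, 0.0) + sign * coef

    add(lhs, -1.0)
    add(rhs, +1.0)
    if not stoich:
        raise ParseError(f"empty stoichiometry in formula {formula!r}")
    return stoich


def format_formula(stoich: dict[str, float]) -> str:
    lhs = [(m, -c) for m, c in stoich.items() if c < 0]
    rhs = [(m, c) for m, c in stoich.items() if c > 0]

    def side(terms):
        return " + ".join(f"{c!r} {m}" for m, c in terms)

    return f"{side(lhs)} -> {side(rhs)}"


# ---------------------------------------------------------------------------
# tabular strain dialect

_MET_COLS = ("id", "name", "compartment", "external", "mu0", "conc_lo", "conc_hi")
_RXN_COLS = ("id", "formula", "lb", "ub", "kind", "objective")


def _opt_float(s: str) -> float | None:
    return float(s) if s not in ("", "NA", "None") else None


def read_strain_tabular(path) -> StrainModel:
    path = Path(path)
    strain_id = path.stem
    metabolites: list[Metabolite] = []
    reactions: list[Reaction] = []
    objective: dict[str, float] = {}
    section = None
    header: list[str] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("# strain:"):
            strain_id = line.split(":", 1)[1].strip()
            continue
        if line.startswith("#"):
            continue
        if line.strip().startswith("["):
            section = line.strip().strip("[]").upper()
            header = []
            if section not in ("METABOLITES", "REACTIONS"):
                raise ParseError(f"{path}:{lineno}: unknown section {section!r}")
            continue
        if section is None:
            raise ParseError(f"{path}:{lineno}: data before any section header")
        fields = line.split("\t")
        if not header:
            header = [h.strip() for h in fields]
            expected = _MET_COLS if section == "METABOLITES" else _RXN_COLS
            if header[0] != "id":
                raise ParseError(f"{path}:{lineno}: first column must be 'id'")
            unknown = set(header) - set(expected)
            if unknown:
                raise ParseError(
                    f"{path}:{lineno}: unknown columns {sorted(unknown)}"
                )
            continue
        row = dict(zip(header, fields))
        try:
            if section == "METABOLITES":
                metabolites.append(Metabolite(
                    id=row["id"],
                    name=row.get("name", ""),
                    compartment=row.get("compartment", ""),
                    external=row.get("external", "0").strip() in ("1", "true", "True"),
                    mu0=_opt_float(row.get("mu0", "")),
                    conc_lo=_opt_float(row.get("conc_lo", "")),
                    conc_hi=_opt_float(row.get("conc_hi", "")),
                ))
            else:
                stoich = parse_formula(row["formula"])
                lb, ub = row.get("lb", ""), row.get("ub", "")
                reversible = any(a in row["formula"] for a in ("<->", "<=>"))
                lb = float(lb) if lb != "" else (-DEFAULT_BOUND if reversible else 0.0)
                ub = float(ub) if ub != "" else DEFAULT_BOUND
                rxn = Reaction(
                    id=row["id"], stoich=stoich, lb=lb, ub=ub,
                    kind=row.get("kind", "internal") or "internal",
                )
                reactions.append(rxn)
                obj = float(row.get("objective", "") or 0.0)
                if obj != 0.0:
                    objective[rxn.id] = obj
        except ParseError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        except (KeyError, ValueError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    model = StrainModel(
        id=strain_id, metabolites=metabolites, reactions=reactions,
        objective=objective,
    )
    model.validate()
    return model


def write_strain_tabular(model: StrainModel, path) -> None:
    lines = [f"# strain: {model.id}", "[METABOLITES]", "\t".join(_MET_COLS)]
    for m in model.metabolites:
        def s(x):
            return "" if x is None else repr(x)
        lines.append("\t".join([
            m.id, m.name, m.compartment, "1" if m.external else "0",
            s(m.mu0), s(m.conc_lo), s(m.conc_hi),
        ]))
    lines += ["", "[REACTIONS]", "\t".join(_RXN_COLS)]
    for r in model.reactions:
        lines.append("\t".join([
            r.id, format_formula(r.stoich), repr(r.lb), repr(r.ub), r.kind,
            repr(model.objective.get(r.id, 0.0)),
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# SBML via cobrapy

def read_strain_sbml(path) -> StrainModel:
    import cobra

    try:
        cm = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra raises various parse errors
        raise ParseError(f"cannot parse SBML file {path}: {exc}") from exc
    objective = {}
    for rxn in cm.reactions:
        coef = rxn.objective_coefficient
        if coef:
            objective[rxn.id] = float(coef)
    metabolites = [
        Metabolite(
            id=m.id, name=m.name or "", compartment=m.compartment or "",
            external=(m.compartment or "").lower() in ("e", "ext", "external", "pool"),
        )
        for m in cm.metabolites
    ]
    reactions = []
    for rxn in cm.reactions:
        if rxn.id in objective:
            kind = "biomass"
        elif rxn.boundary:
            kind = "exchange"
        else:
            kind = "internal"
        reactions.append(Reaction(
            id=rxn.id,
            stoich={m.id: float(c) for m, c in rxn.metabolites.items()},
            lb=float(rxn.lower_bound), ub=float(rxn.upper_bound), kind=kind,
        ))
    model = StrainModel(
        id=cm.id or Path(path).stem, metabolites=metabolites,
        reactions=reactions, objective=objective,
    )
    model.validate()
    return model


def write_strain_sbml(model: StrainModel, path) -> None:
    import cobra

    cm = cobra.Model(model.id)
    comp = {True: "e", False: "c"}
    cmets = {}
    for m in model.metabolites:
        cmets[m.id] = cobra.Metabolite(
            m.id, name=m.name, compartment=m.compartment or comp[m.external]
        )
    cm.add_metabolites(list(cmets.values()))
    for r in model.reactions:
        rxn = cobra.Reaction(r.id, lower_bound=r.lb, upper_bound=r.ub)
        cm.add_reactions([rxn])
        rxn.add_metabolites({cmets[m]: c for m, c in r.stoich.items()})
    cm.objective = {
        cm.reactions.get_by_id(rid): coef for rid, coef in model.objective.items()
    }
    cobra.io.write_sbml_model(cm, str(path))


def read_strain_model(path, format: str = "tabular") -> StrainModel:
    """Read a strain CBM from ``tabular`` (TSV) or ``sbml`` dialects."""
    if format == "tabular":
        return read_strain_tabular(path)
    if format == "sbml":
        return read_strain_sbml(path)
    raise ValidationError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# community JSON

def _strain_to_dict(s: StrainModel) -> dict:
    return {
        "id": s.id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment,
             "external": m.external, "mu0": m.mu0,
             "conc_lo": m.conc_lo, "conc_hi": m.conc_hi}
            for m in s.metabolites
        ],
        "reactions": [
            {"id": r.id, "stoich": r.stoich, "lb": r.lb, "ub": r.ub,
             "kind": r.kind}
            for r in s.reactions
        ],
        "objective": s.objective,
    }


def _strain_from_dict(d: dict) -> StrainModel:
    return StrainModel(
        id=d["id"],
        metabolites=[Metabolite(**m) for m in d["metabolites"]],
        reactions=[Reaction(**r) for r in d["reactions"]],
        objective={k: float(v) for k, v in d["objective"].items()},
    )


def write_community(model: CommunityModel, path) -> None:
    model.validate()
    doc = {
        "strains": [_strain_to_dict(s) for s in model.strains],
        "pool": {
            "shared": model.pool.shared,
            "env_exchange": {m: list(b) for m, b in model.pool.env_exchange.items()},
        },
        "couplings": [
            {"terms": [list(t) for t in c.terms], "rhs": c.rhs,
             "relation": c.relation}
            for c in model.couplings
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_community(path) -> CommunityModel:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON at line {exc.lineno}") from exc
    try:
        model = CommunityModel(
            strains=[_strain_from_dict(d) for d in doc["strains"]],
            pool=PoolSpec(
                shared=list(doc["pool"]["shared"]),
                env_exchange={
                    m: (float(b[0]), float(b[1]))
                    for m, b in doc["pool"]["env_exchange"].items()
                },
            ),
            couplings=[
                LinearCoupling(
                    terms=[(t[0], t[1], float(t[2])) for t in c["terms"]],
                    rhs=float(c["rhs"]), relation=c["relation"],
                )
                for c in doc.get("couplings", [])
            ],
        )
    except (KeyError, TypeError) as exc:
        raise ParseError(f"{path}: malformed community document: {exc}") from exc
    model.validate()
    return model


# ---------------------------------------------------------------------------
# thermodynamic tables

def read_thermo_table(path) -> ThermoTable:
    entries = {}
    temperature = 348.15
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if line.startswith("# temperature_K:"):
            temperature = float(line.split(":", 1)[1])
            continue
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0] == "metabolite":
            continue
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected 3 columns")
        try:
            entries[fields[0]] = (float(fields[1]), float(fields[2]))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    table = ThermoTable(entries=entries, temperature=temperature)
    table.validate()
    return table


def write_thermo_table(table: ThermoTable, path) -> None:
    lines = [f"# temperature_K: {table.temperature!r}",
             "metabolite\tmu0_kJ_mol\tdg_kJ_mol"]
    for met, (mu0, dg) in table.entries.items():
        lines.append(f"{met}\t{mu0!r}\t{dg!r}")
    Path(path).write_text("\n".join(lines) + "\n")
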