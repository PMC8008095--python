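"""Tabular, SBML, DOT and edge-list export of reaction networks.

All writers are deterministic: rows, species and edges are emitted in a
fixed order derived from generations and canonical identifiers, and no
timestamps appear in the output, so repeated exports of the same network
are byte-identical.
"""

from __future__ import annotations

import csv
import io
from xml.etree import ElementTree as ET

from .errors import GangliosimError, NoNameError
from .network import Network
from .nomenclature import (SSN_TO_LEGACY, iupac_ganglioside_name, series_of,
                           systematic_svennerholm)
from .structures import Structure

#: Small-molecule species: donor/byproduct code -> (SBML id, display name,
#: ChEBI identifier).  A static table; no network lookups.
SMALL_MOLECULES = {
    "UDP-G": ("UDP_Glc", "UDP-Glc", "CHEBI:46229"),
    "UDP-L": ("UDP_Gal", "UDP-Gal", "CHEBI:66914"),
    "UDP-V": ("UDP_GalNAc", "UDP-GalNAc", "CHEBI:67138"),
    "CMP-S": ("CMP_Neu5Ac", "CMP-Neu5Ac", "CHEBI:57812"),
    "UDP": ("UDP", "UDP", "CHEBI:58223"),
    "CMP": ("CMP", "CMP", "CHEBI:60377"),
}

#: Edge colors by transferred sugar (one class per transferase family):
#: galactosyl yellow, glucosyl blue, N-acetylgalactosaminyl brown,
#: sialyl magenta.
SUGAR_COLORS = {"L": "gold", "G": "blue", "V": "brown", "S": "magenta"}

_SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
_ANNOT_NS = "urn:gangliosim:annotations"


def _open_dest(destination):
    """Accept a path or a writable text file object."""
    if hasattr(destination, "write"):
        return destination, False
    try:
        return open(destination, "w", encoding="utf-8", newline=""), True
    except OSError as exc:
        raise GangliosimError(f"cannot write to {destination!r}: {exc}") from exc


CSV_COLUMNS = ["identifier_abbrev", "identifier_full", "ssn", "legacy_name",
               "iupac_name", "generation", "sialo_count", "series",
               "core_number"]


def export_records(net: Network) -> list[dict[str, object]]:
    """One record per non-seed network node, in deterministic row order
    (generation, then identifier)."""
    records = []
    for nid in sorted(net.products, key=lambda n: (net.generation(n), n)):
        s = net.structure(nid)
        try:
            ssn = str(systematic_svennerholm(s))
            legacy = SSN_TO_LEGACY.get(ssn, ssn)
            iupac = iupac_ganglioside_name(s)
            core_number = str(s.core_info().core_number)
        except NoNameError:
            # glucosylceramide precedes the naming system's cores
            ssn = legacy = ""
            iupac = s.to_iupac_condensed()
            core_number = str(s.core_info().core_number)
        records.append({
            "identifier_abbrev": nid,
            "identifier_full": s.full,
            "ssn": ssn,
            "legacy_name": legacy,
            "iupac_name": iupac,
            "generation": net.generation(nid),
            "sialo_count": s.count_residues("S"),
            "series": series_of(s) or "precursor",
            "core_number": core_number,
        })
    return records


def write_csv(net: Network, destination) -> int:
    """Write the structure table (RFC 4180). Returns the row count."""
    fh, close = _open_dest(destination)
    try:
        writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS,
                                lineterminator="\r\n")
        writer.writeheader()
        records = export_records(net)
        writer.writerows(records)
        return len(records)
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# SBML

def glycan_species_id(identifier: str) -> str:
    """Deterministic, reversible SBML id for a structure identifier
    (brackets escape to ``_b_``/``_e_``)."""
    return "x_" + identifier.replace("[", "_b_").replace("]", "_e_")


def identifier_from_species_id(species_id: str) -> str:
    if not species_id.startswith("x_"):
        raise GangliosimError(f"{species_id!r} is not a glycan species id")
    return species_id[2:].replace("_b_", "[").replace("_e_", "]")


def write_sbml(net: Network, destination) -> int:
    """Write the network as SBML Level 3 Version 1 core.

    One species per glycan (seed included) in a single "golgi"
    compartment, plus one species per nucleotide-sugar donor and
    nucleotide byproduct in use; one irreversible reaction per edge with
    the donor as co-reactant and the nucleotide as co-product, all
    stoichiometries 1.  Returns the number of species written.
    """
    ET.register_namespace("", _SBML_NS)
    sbml = ET.Element(f"{{{_SBML_NS}}}sbml", {"level": "3", "version": "1"})
    model = ET.SubElement(sbml, f"{{{_SBML_NS}}}model",
                          {"id": "ganglioside_biosynthesis",
                           "name": "Ganglioside biosynthesis network"})
    comps = ET.SubElement(model, f"{{{_SBML_NS}}}listOfCompartments")
    ET.SubElement(comps, f"{{{_SBML_NS}}}compartment",
                  {"id": "golgi", "spatialDimensions": "3", "size": "1",
                   "constant": "true"})

    events = net.events()
    species_list = ET.SubElement(model, f"{{{_SBML_NS}}}listOfSpecies")
    n_species = 0

    def add_species(sid: str, name: str, chebi: str | None = None) -> None:
        nonlocal n_species
        sp = ET.SubElement(species_list, f"{{{_SBML_NS}}}species",
                           {"id": sid, "name": name, "compartment": "golgi",
                            "hasOnlySubstanceUnits": "false",
                            "boundaryCondition": "false", "constant": "false"})
        if chebi:
            annot = ET.SubElement(sp, f"{{{_SBML_NS}}}annotation")
            ET.SubElement(annot, f"{{{_ANNOT_NS}}}identifier",
                          {"chebi": chebi})
        n_species += 1

    ordered_nodes = sorted(net.graph.nodes,
                           key=lambda n: (net.generation(n), n))
    for nid in ordered_nodes:
        add_species(glycan_species_id(nid), nid)
    used = {e.donor for e in events} | {e.byproduct for e in events}
    for code in ("UDP-G", "UDP-L", "UDP-V", "CMP-S", "UDP", "CMP"):
        if code in used:
            sid, name, chebi = SMALL_MOLECULES[code]
            add_species(sid, name, chebi)

    reactions = ET.SubElement(model, f"{{{_SBML_NS}}}listOfReactions")
    for i, ev in enumerate(events, 1):
        rx = ET.SubElement(reactions, f"{{{_SBML_NS}}}reaction",
                           {"id": f"R{i:03d}_E{ev.enzyme_number}",
                            "name": f"enzyme {ev.enzyme_number}",
                            "reversible": "false"})
        reactants = ET.SubElement(rx, f"{{{_SBML_NS}}}listOfReactants")
        products = ET.SubElement(rx, f"{{{_SBML_NS}}}listOfProducts")
        for parent, sid in (
                (reactants, glycan_species_id(ev.substrate.abbreviated)),
                (reactants, SMALL_MOLECULES[ev.donor][0]),
                (products, glycan_species_id(ev.product.abbreviated)),
                (products, SMALL_MOLECULES[ev.byproduct][0])):
            ET.SubElement(parent, f"{{{_SBML_NS}}}speciesReference",
                          {"species": sid, "stoichiometry": "1",
                           "constant": "true"})

    ET.indent(sbml)
    text = ET.tostring(sbml, encoding="unicode", xml_declaration=True)
    fh, close = _open_dest(destination)
    try:
        fh.write(text + "\n")
    finally:
        if close:
            fh.close()
    return n_species


def read_sbml_edges(source) -> set[tuple[str, int, str]]:
    """Rebuild (substrate, enzyme, product) triples from an SBML file
    written by :func:`write_sbml` (round-trip check / Copasi-free import)."""
    tree = ET.parse(source)
    triples: set[tuple[str, int, str]] = set()
    for rx in tree.iter(f"{{{_SBML_NS}}}reaction"):
        enzyme = int(rx.get("id", "").rsplit("_E", 1)[1])
        substrate = product = None
        for ref in rx.find(f"{{{_SBML_NS}}}listOfReactants") or ():
            sid = ref.get("species", "")
            if sid.startswith("x_"):
                substrate = identifier_from_species_id(sid)
        for ref in rx.find(f"{{{_SBML_NS}}}listOfProducts") or ():
            sid = ref.get("species", "")
            if sid.startswith("x_"):
                product = identifier_from_species_id(sid)
        if substrate is None or product is None:
            raise GangliosimError("reaction without glycan reactant/product")
        triples.add((substrate, enzyme, product))
    return triples


# ---------------------------------------------------------------------------
# DOT / edge list

def write_dot(net: Network, destination) -> int:
    """Graphviz DOT digraph, edges colored by transferred sugar.

    Nodes are labelled with the systematic Svennerholm name where one is
    defined, with the identifier beneath.  Returns the edge count.
    """
    lines = ["digraph gangliosides {", "  rankdir=LR;",
             '  node [shape=box, fontsize=10];']
    for nid in sorted(net.graph.nodes, key=lambda n: (net.generation(n), n)):
        try:
            label = f"{systematic_svennerholm(net.structure(nid))}\\n{nid}"
        except NoNameError:
            label = nid
        lines.append(f'  "{nid}" [label="{label}"];')
    events = net.events()
    for ev in events:
        color = SUGAR_COLORS[ev.donor.split("-")[1]]
        lines.append(f'  "{ev.substrate.abbreviated}" -> '
                     f'"{ev.product.abbreviated}" '
                     f'[color={color}, label="{ev.enzyme_number}"];')
    lines.append("}")
    fh, close = _open_dest(destination)
    try:
        fh.write("\n".join(lines) + "\n")
    finally:
        if close:
            fh.close()
    return len(events)


def write_edgelist(net: Network, destination) -> int:
    """Plain-text edge list: substrate, enzyme number, EC, product
    (tab-separated). Returns the edge count."""
    from .rules import default_ruleset
    ruleset = net.config.ruleset if net.config else default_ruleset()
    rules = {r.number: r for r in ruleset}
    fh, close = _open_dest(destination)
    try:
        count = 0
        for ev in net.events():
            ec = rules[ev.enzyme_number].ec if ev.enzyme_number in rules else ""
            fh.write(f"{ev.substrate.abbreviated}\t{ev.enzyme_number}\t{ec}\t"
                     f"{ev.product.abbreviated}\n")
            count += 1
        return count
    finally:
        if close:
            fh.close()


def render_csv(net: Network) -> str:
    """The CSV table as a string (convenience for the CLI)."""
    buf = io.StringIO()
    write_csv(net, buf)
    return buf.getvalue()
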