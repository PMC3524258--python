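"""BNGL-subset text export of a generated network, and a reader for it.

The exported file carries molecule types, seed species and the flat
unidirectional reaction list, so the network can be compared against
rule-based modeling tools.  Locations are rendered as ``@raft`` /
``@nonraft`` / ``@cytosol`` / ``@bath`` suffixes on species labels.
"""

from __future__ import annotations

from pathlib import Path

from .network import ReactionNetwork

__all__ = ["export_bngl_subset", "read_bngl_subset"]


def export_bngl_subset(network: ReactionNetwork, path) -> None:
    """Write molecule types, species and reactions as a BNGL-like text file."""
    path = Path(path)
    lines: list[str] = ["# generated reaction network (BNGL subset)", ""]
    lines.append("begin molecule types")
    for mt in network.model.molecule_types:
        toks = []
        for s in mt.sites:
            if s.name == "l" and mt.name == "Syk" \
                    and not network.model.params.syk_linker_site:
                continue
            tok = s.name
            if s.states:
                tok += "".join(f"~{st}" for st in s.states)
            toks.append(tok)
        lines.append(f"  {mt.name}({','.join(toks)})")
    lines.append("end molecule types")
    lines.append("")
    lines.append("begin species")
    for sp in network.species:
        lines.append(f"  {sp.index + 1} {sp.label}@{sp.location}")
    lines.append("end species")
    lines.append("")
    lines.append("begin reactions")
    for i, rxn in enumerate(network.reactions):
        r = ",".join(str(j + 1) for j in rxn.reactants)
        p = ",".join(str(j + 1) for j in rxn.products)
        extra = f" bath={rxn.bath}" if rxn.bath else ""
        extra += f" km={rxn.km:g}" if rxn.km is not None else ""
        lines.append(f"  {i + 1} {r} {p} {rxn.rate:.12g} {rxn.kind}{extra} # {rxn.tag}")
    lines.append("end reactions")
    path.write_text("\n".join(lines) + "\n")


def read_bngl_subset(path) -> dict:
    """Re-parse an exported network file.

    Returns molecule-type lines, the set of (label, location) species keys
    and the reaction tuples — enough for round-trip identity checks.
    """
    section = None
    molecule_types: list[str] = []
    species: set[tuple[str, str]] = set()
    reactions: list[tuple] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip() if not raw.strip().startswith("#") \
            else ""
        if not line:
            continue
        if line.startswith("begin "):
            section = line.split(None, 1)[1]
            continue
        if line.startswith("end "):
            section = None
            continue
        if section == "molecule types":
            molecule_types.append(line)
        elif section == "species":
            _, spec = line.split(None, 1)
            label, loc = spec.rsplit("@", 1)
            species.add((label, loc))
        elif section == "reactions":
            parts = line.split()
            idx, r, p, rate, kind = parts[:5]
            reactions.append((
                tuple(int(x) for x in r.split(",")),
                tuple(int(x) for x in p.split(",")),
                float(rate), kind,
            ))
    return {
        "molecule_types": molecule_types,
        "species": species,
        "reactions": reactions,
    }
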