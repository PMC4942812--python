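"""Genome-scale metabolic network model.

A deliberately small data model in the spirit of Recon-style human
reconstructions: reactions carry flat gene links (no boolean
gene-protein-reaction logic), metabolites are compartment instances
(``glc[c]`` and ``glc[e]`` are distinct), and every entity gets a
deterministic 1-based ``network_index`` (lexicographic by identifier)
that downstream feature builders use as a categorical proxy for the
entity's position in the model.

The on-disk format is a flat TSV, one reaction per row, with
semicolon-delimited list fields and metabolite tokens suffixed with
their compartment in square brackets.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

CYTOSOL = "c"

NETWORK_COLUMNS = [
    "reaction_id", "genes", "substrates", "products",
    "reversible", "delta_g0", "pathway",
]

_TOKEN_RE = re.compile(r"^(?P<base>[^\[\]]+)(\[(?P<comp>[^\[\]]+)\])?$")


class NetworkValidationError(ValueError):
    """Structural problem in a network table; ``offenders`` lists the ids."""

    def __init__(self, message: str, offenders=()):
        self.offenders = sorted(offenders)
        if self.offenders:
            message = f"{message}: {', '.join(self.offenders)}"
        super().__init__(message)


class AmbiguousMappingError(ValueError):
    """One measured identifier matches more than one network entity."""


@dataclass(frozen=True)
class Metabolite:
    metabolite_id: str            # full token, e.g. "glc[c]"
    compartment: str
    network_index: int
    hmdb_id: str | None = None
    kegg_id: str | None = None


@dataclass(frozen=True)
class Gene:
    gene_id: str
    network_index: int
    entrez_id: str | None = None


@dataclass(frozen=True)
class Reaction:
    reaction_id: str
    network_index: int
    pathway_id: int
    delta_g0: float
    reversible: bool
    substrates: frozenset[str]
    products: frozenset[str]
    genes: frozenset[str]

    @property
    def metabolites(self) -> frozenset[str]:
        return self.substrates | self.products


@dataclass
class MetabolicNetwork:
    metabolites: dict[str, Metabolite]
    genes: dict[str, Gene]
    reactions: dict[str, Reaction]
    compartments: set[str]
    pathway_names: dict[int, str] = field(default_factory=dict)

    def reactions_sorted(self) -> list[Reaction]:
        return sorted(self.reactions.values(), key=lambda r: r.network_index)

    def gene_pathways(self, gene_id: str) -> set[int]:
        """Every pathway of every reaction the gene catalyzes."""
        return {r.pathway_id for r in self.reactions.values() if gene_id in r.genes}

    def validate(self) -> None:
        dangling = set()
        for r in self.reactions.values():
            dangling |= {g for g in r.genes if g not in self.genes}
            dangling |= {m for m in r.metabolites if m not in self.metabolites}
        if dangling:
            raise NetworkValidationError("undeclared entities referenced", dangling)
        for entities in (self.metabolites, self.genes, self.reactions):
            idx = [e.network_index for e in entities.values()]
            if sorted(idx) != list(range(1, len(idx) + 1)):
                raise NetworkValidationError("network indices not contiguous from 1")


@dataclass(frozen=True)
class GMPair:
    """A connected gene-metabolite pair: the gene's enzyme catalyzes at
    least one reaction that consumes or produces the metabolite."""
    gene_id: str
    metabolite_id: str
    connecting_reaction_ids: frozenset[str]


@dataclass(frozen=True)
class RGMTriplet:
    reaction_id: str
    gene_id: str
    metabolite_id: str
    is_substrate: bool

    @property
    def key(self) -> tuple[str, str, str, bool]:
        return (self.reaction_id, self.gene_id, self.metabolite_id, self.is_substrate)


def parse_metabolite_token(token: str) -> tuple[str, str]:
    """Split ``base[comp]`` into (full token, compartment); bare tokens are
    cytosolic."""
    m = _TOKEN_RE.match(token.strip())
    if m is None or not m.group("base"):
        raise NetworkValidationError(f"malformed metabolite token {token!r}")
    comp = m.group("comp") or CYTOSOL
    return f"{m.group('base')}[{comp}]", comp


def _split_list(cell) -> list[str]:
    if pd.isna(cell) or str(cell).strip() == "":
        return []
    return [t.strip() for t in str(cell).split(";") if t.strip()]


def load_network(
    network_table,
    gene_annotations=None,
    metabolite_annotations=None,
) -> MetabolicNetwork:
    """Load and validate a network TSV (or DataFrame with the same columns).

    Optional annotation tables declare the entity universe and external
    keys: genes (gene_id, entrez_id), metabolites (metabolite_id, hmdb_id,
    kegg_id).  When given, a reaction referencing an undeclared entity is
    a validation error; otherwise the universe is inferred from the
    reaction rows.  Indices are assigned lexicographically (1-based) and
    pathway labels are coded by first appearance, so loading is
    deterministic and idempotent.
    """
    df = network_table if isinstance(network_table, pd.DataFrame) \
        else pd.read_csv(network_table, sep="\t", dtype=str)
    missing = [c for c in NETWORK_COLUMNS if c not in df.columns]
    if missing:
        raise NetworkValidationError("missing columns", missing)
    if df["reaction_id"].duplicated().any():
        dups = df.loc[df["reaction_id"].duplicated(), "reaction_id"]
        raise NetworkValidationError("duplicate reaction ids", set(dups))

    gene_ann = _read_annotation(gene_annotations, "gene_id")
    met_ann = _read_annotation(metabolite_annotations, "metabolite_id")

    rows = []
    seen_genes: set[str] = set()
    seen_mets: dict[str, str] = {}
    pathway_codes: dict[str, int] = {}
    for _, row in df.iterrows():
        genes = _split_list(row["genes"])
        subs, prods = [], []
        for col, acc in (("substrates", subs), ("products", prods)):
            for tok in _split_list(row[col]):
                met, comp = parse_metabolite_token(tok)
                seen_mets[met] = comp
                acc.append(met)
        seen_genes.update(genes)
        label = str(row["pathway"])
        if label not in pathway_codes:
            pathway_codes[label] = len(pathway_codes)
        rows.append((row, genes, subs, prods, pathway_codes[label]))

    if gene_ann is not None:
        declared = set(gene_ann.index)
        undeclared = seen_genes - declared
        if undeclared:
            raise NetworkValidationError("undeclared genes referenced", undeclared)
        seen_genes = declared | seen_genes
    if met_ann is not None:
        declared = set(met_ann.index)
        undeclared = set(seen_mets) - declared
        if undeclared:
            raise NetworkValidationError("undeclared metabolites referenced", undeclared)
        for met in declared - set(seen_mets):
            seen_mets[met] = parse_metabolite_token(met)[1]

    genes = {
        g: Gene(g, i, entrez_id=_ann_value(gene_ann, g, "entrez_id"))
        for i, g in enumerate(sorted(seen_genes), start=1)
    }
    metabolites = {
        m: Metabolite(m, seen_mets[m], i,
                      hmdb_id=_ann_value(met_ann, m, "hmdb_id"),
                      kegg_id=_ann_value(met_ann, m, "kegg_id"))
        for i, m in enumerate(sorted(seen_mets), start=1)
    }
    reactions = {}
    order = sorted(range(len(rows)), key=lambda i: str(rows[i][0]["reaction_id"]))
    for idx, i in enumerate(order, start=1):
        row, rgenes, subs, prods, pw = rows[i]
        reactions[str(row["reaction_id"])] = Reaction(
            reaction_id=str(row["reaction_id"]),
            network_index=idx,
            pathway_id=pw,
            delta_g0=float(row["delta_g0"]),
            reversible=bool(int(row["reversible"])),
            substrates=frozenset(subs),
            products=frozenset(prods),
            genes=frozenset(rgenes),
        )
    net = MetabolicNetwork(
        metabolites=metabolites,
        genes=genes,
        reactions=reactions,
        compartments=set(seen_mets.values()),
        pathway_names={v: k for k, v in pathway_codes.items()},
    )
    net.validate()
    return net


def _read_annotation(source, index_col):
    if source is None:
        return None
    df = source if isinstance(source, pd.DataFrame) \
        else pd.read_csv(source, sep="\t", dtype=str)
    return df.set_index(index_col)


def _ann_value(ann, key, col):
    if ann is None or key not in ann.index or col not in ann.columns:
        return None
    v = ann.loc[key, col]
    return None if pd.isna(v) else str(v)


def write_network(network: MetabolicNetwork, path) -> None:
    """Write the reaction table back to TSV (round-trips through
    load_network up to index assignment, which is order-free)."""
    rows = []
    for r in network.reactions_sorted():
        rows.append({
            "reaction_id": r.reaction_id,
            "genes": ";".join(sorted(r.genes)),
            "substrates": ";".join(sorted(r.substrates)),
            "products": ";".join(sorted(r.products)),
            "reversible": int(r.reversible),
            "delta_g0": repr(r.delta_g0),
            "pathway": network.pathway_names.get(r.pathway_id, str(r.pathway_id)),
        })
    pd.DataFrame(rows, columns=NETWORK_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Omics identifier mapping
# ---------------------------------------------------------------------------

@dataclass
class MappingReport:
    gene_map: dict[str, str]
    metabolite_map: dict[str, str]
    unmapped_genes: list[str]
    unmapped_metabolites: list[str]


def map_omics_ids(
    network: MetabolicNetwork,
    measured_gene_ids,
    measured_metabolite_ids,
    id_map,
) -> MappingReport:
    """Map measured omics identifiers onto network entities.

    ``id_map`` is a table (measured_id, key_type in {HMDB, KEGG, ENTREZ},
    network_id).  Metabolites map first through their HMDB key and only
    fall back to KEGG when no HMDB match exists; genes map through
    ENTREZ.  A measured id whose key matches two distinct network
    entities raises AmbiguousMappingError rather than choosing silently.
    """
    df = id_map if isinstance(id_map, pd.DataFrame) \
        else pd.read_csv(id_map, sep="\t", dtype=str)
    by_key: dict[tuple[str, str], set[str]] = {}
    for _, row in df.iterrows():
        by_key.setdefault((str(row["measured_id"]), str(row["key_type"]).upper()),
                          set()).add(str(row["network_id"]))

    def resolve(mid: str, key_type: str, universe) -> str | None:
        targets = {t for t in by_key.get((mid, key_type), set()) if t in universe}
        if len(targets) > 1:
            raise AmbiguousMappingError(
                f"{key_type} key of {mid!r} matches several network entities: "
                f"{sorted(targets)}")
        return next(iter(targets)) if targets else None

    metabolite_map, unmapped_mets = {}, []
    for mid in measured_metabolite_ids:
        hit = resolve(str(mid), "HMDB", network.metabolites)
        if hit is None:
            hit = resolve(str(mid), "KEGG", network.metabolites)
        if hit is None:
            unmapped_mets.append(str(mid))
        else:
            metabolite_map[str(mid)] = hit

    gene_map, unmapped_genes = {}, []
    for gid in measured_gene_ids:
        hit = resolve(str(gid), "ENTREZ", network.genes)
        if hit is None:
            unmapped_genes.append(str(gid))
        else:
            gene_map[str(gid)] = hit

    return MappingReport(gene_map, metabolite_map, unmapped_genes, unmapped_mets)


# ---------------------------------------------------------------------------
# Connected pairs and RGM triplets
# ---------------------------------------------------------------------------

def connected_gm_pairs(
    network: MetabolicNetwork,
    metabolite_compartment_filter: str | None = None,
) -> list[GMPair]:
    """All (gene, metabolite) pairs sharing at least one reaction, each with
    its full set of connecting reactions.  With a compartment filter only
    metabolites of that compartment are kept."""
    acc: dict[tuple[str, str], set[str]] = {}
    for r in network.reactions.values():
        for g in r.genes:
            for m in r.metabolites:
                if metabolite_compartment_filter is not None and \
                        network.metabolites[m].compartment != metabolite_compartment_filter:
                    continue
                acc.setdefault((g, m), set()).add(r.reaction_id)
    pairs = [GMPair(g, m, frozenset(rs)) for (g, m), rs in acc.items()]
    pairs.sort(key=lambda p: (network.genes[p.gene_id].network_index,
                              network.metabolites[p.metabolite_id].network_index))
    return pairs


def enumerate_rgm_triplets(
    network: MetabolicNetwork,
    extend_compartments: bool = False,
) -> list[RGMTriplet]:
    """One triplet per (reaction, catalyzing gene, participating metabolite,
    role).  Cytosolic metabolites only unless ``extend_compartments``; a
    metabolite that is both substrate and product of a reaction yields
    two triplets, one per role.  Ordering is deterministic: reaction
    index, gene index, metabolite index, substrate before product."""
    out: list[RGMTriplet] = []
    for r in network.reactions_sorted():
        genes = sorted(r.genes, key=lambda g: network.genes[g].network_index)
        mets = sorted(r.metabolites,
                      key=lambda m: network.metabolites[m].network_index)
        for g in genes:
            for m in mets:
                if not extend_compartments and \
                        network.metabolites[m].compartment != CYTOSOL:
                    continue
                if m in r.substrates:
                    out.append(RGMTriplet(r.reaction_id, g, m, True))
                if m in r.products:
                    out.append(RGMTriplet(r.reaction_id, g, m, False))
    return out
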