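"""Synthetic cohorts with planted enzyme-metabolite couplings.

The generator emulates the structure of a matched two-condition
(noncancerous / cancer) transcriptome + metabolome study on a small
random metabolic network: a tunable fraction of metabolites is coupled
to the expression of one of its catalyzing genes, couplings are
condition-specific and preferentially localized to a "hot" pathway,
coupled genes carry inflated expression variance, and clinical tables
plant exponential proportional-hazards survival links and an
estrogen-receptor-like binary label on chosen metabolites.

Coupling is imposed on the Gaussian copula scale and then pushed through
a monotone (exponential) transform, so the planted strength rho_target
is the population Spearman correlation of the pair.  Each coupled
metabolite has exactly one driving gene per planting, which keeps
rho_target exact; the coupling fraction therefore counts *metabolites*
(one planted pair each), not raw connected pairs.

Everything is driven by a single integer seed through one
numpy Generator, so identical seeds give byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .network import (
    CYTOSOL, MetabolicNetwork, connected_gm_pairs, load_network,
)

NONCANCEROUS = "noncancerous"
CANCER = "cancer"
BOTH = "both"

DEFAULT_COUPLING_FRACTIONS = {NONCANCEROUS: 0.0, CANCER: 0.4}


@dataclass(frozen=True)
class CoupledPair:
    gene_id: str
    metabolite_id: str
    condition: str                # noncancerous | cancer | both
    strength: float               # attained population Spearman rho, (0, 1]
    sign: int                     # +1 or -1
    primary: bool = True          # primary driver vs co-regulated secondary


@dataclass
class SyntheticTruth:
    """Planted ground truth; the recovery-test oracle."""
    coupled_pairs: list[CoupledPair]
    hazard_links: list[tuple[str, float]]     # (metabolite_id, log hazard coef)
    er_link: tuple[str, float] | None         # (metabolite_id, logit shift)
    pathway_hot: int | None
    seed: int

    def coupled_metabolites(self, condition: str | None = None) -> set[str]:
        return {
            cp.metabolite_id for cp in self.coupled_pairs
            if condition is None or cp.condition in (condition, BOTH)
        }

    def to_json(self, path) -> None:
        payload = {
            "coupled_pairs": [dataclasses.asdict(cp) for cp in self.coupled_pairs],
            "hazard_links": [list(h) for h in self.hazard_links],
            "er_link": list(self.er_link) if self.er_link else None,
            "pathway_hot": self.pathway_hot,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            coupled_pairs=[CoupledPair(**cp) for cp in d["coupled_pairs"]],
            hazard_links=[(m, float(c)) for m, c in d["hazard_links"]],
            er_link=tuple(d["er_link"]) if d["er_link"] else None,
            pathway_hot=d["pathway_hot"],
            seed=d["seed"],
        )


@dataclass
class OmicsCohort:
    """Matched omics over one shared, ordered sample axis."""
    expression: pd.DataFrame      # genes x samples, log-scale a.u.
    metabolites: pd.DataFrame     # metabolites x samples, positive abundances
    condition: pd.Series          # per-sample label
    survival_time: pd.Series | None = None   # months
    event: pd.Series | None = None
    er_status: pd.Series | None = None

    @property
    def samples(self) -> pd.Index:
        return self.expression.columns

    def sample_mask(self, stratum: str) -> np.ndarray:
        if stratum == "all":
            return np.ones(len(self.samples), dtype=bool)
        return (self.condition.loc[self.samples] == stratum).to_numpy()


# ---------------------------------------------------------------------------
# Network generation
# ---------------------------------------------------------------------------

def generate_network(
    n_reactions: int,
    n_genes: int,
    n_metabolites: int,
    n_pathways: int,
    seed: int,
    reversible_prob: float = 0.3,
    delta_g0_sd: float = 10.0,
    noncytosol_fraction: float = 0.15,
) -> MetabolicNetwork:
    """Random bipartite-via-reactions network.

    Each reaction draws 1-3 genes, 1-3 substrates and 1-2 products
    uniformly (substrates and products disjoint within a reaction),
    reversibility ~ Bernoulli(reversible_prob), delta_g0 ~ Normal(0,
    delta_g0_sd) kJ/mol; pathways are contiguous blocks of reactions.
    A trailing fraction of metabolites lives outside the cytosol
    (compartment "e") so compartment filtering has something to filter.
    """
    if min(n_reactions, n_genes, n_metabolites, n_pathways) < 1:
        raise ValueError("all sizes must be >= 1")
    rng = np.random.default_rng(seed)
    width = max(4, len(str(max(n_reactions, n_genes, n_metabolites))))
    gene_ids = [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]
    n_cyt = max(1, n_metabolites - int(round(noncytosol_fraction * n_metabolites)))
    met_ids = [f"M{i:0{width}d}[{'c' if i <= n_cyt else 'e'}]"
               for i in range(1, n_metabolites + 1)]

    block = math.ceil(n_reactions / n_pathways)
    rows = []
    for i in range(1, n_reactions + 1):
        n_g = int(rng.integers(1, min(3, n_genes) + 1))
        genes = rng.choice(gene_ids, size=n_g, replace=False)
        if n_metabolites == 1:
            subs = prods = list(met_ids)   # degenerate: dual-role transport
        else:
            n_s = int(rng.integers(1, min(3, n_metabolites - 1) + 1))
            n_p = int(rng.integers(1, min(2, n_metabolites - n_s) + 1))
            mets = rng.choice(met_ids, size=n_s + n_p, replace=False)
            subs, prods = list(mets[:n_s]), list(mets[n_s:])
        rows.append({
            "reaction_id": f"R{i:0{width}d}",
            "genes": ";".join(sorted(genes)),
            "substrates": ";".join(sorted(subs)),
            "products": ";".join(sorted(prods)),
            "reversible": int(rng.random() < reversible_prob),
            "delta_g0": repr(float(rng.normal(0.0, delta_g0_sd))),
            "pathway": f"PWY{(i - 1) // block:03d}",
        })
    return load_network(pd.DataFrame(rows))


def exact_id_map(network: MetabolicNetwork) -> pd.DataFrame:
    """Identity id-map table for synthetic cohorts whose measured ids are
    the network ids themselves (HMDB rows for metabolites, ENTREZ for
    genes)."""
    rows = [{"measured_id": m, "key_type": "HMDB", "network_id": m}
            for m in sorted(network.metabolites)]
    rows += [{"measured_id": g, "key_type": "ENTREZ", "network_id": g}
             for g in sorted(network.genes)]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Omics generation
# ---------------------------------------------------------------------------

def _mixed_role(network: MetabolicNetwork, metabolite_id: str,
                reaction_ids) -> bool:
    roles = set()
    for rid in reaction_ids:
        r = network.reactions[rid]
        if metabolite_id in r.substrates:
            roles.add("s")
        if metabolite_id in r.products:
            roles.add("p")
    return len(roles) > 1


def _majority_role_sign(network: MetabolicNetwork, gene_id: str,
                        metabolite_id: str, reaction_ids) -> int:
    """+1 when the metabolite is at least as often a product as a substrate
    across the pair's connecting reactions (product roles read positive)."""
    n_sub = n_prod = 0
    for rid in reaction_ids:
        r = network.reactions[rid]
        if metabolite_id in r.substrates:
            n_sub += 1
        if metabolite_id in r.products:
            n_prod += 1
    return 1 if n_prod >= n_sub else -1


def generate_omics(
    network: MetabolicNetwork,
    n_samples_per_condition: int = 50,
    coupling_fraction_by_condition: dict[str, float] | None = None,
    strength_range: tuple[float, float] = (0.5, 0.9),
    noise_sd: float = 1.0,
    variance_multiplier: float = 2.0,
    pathway_hot: int | None = None,
    pathway_bias: float = 0.5,
    sign_policy: str = "metabolite",
    secondary_range: tuple[float, float] | None = (0.4, 0.8),
    max_secondary: int = 5,
    n_hazard_metabolites: int = 3,
    hazard_log_hr: float = math.log(2.0),
    er_shift: float | None = 2.0,
    seed: int = 0,
) -> tuple[OmicsCohort, SyntheticTruth]:
    """Two-condition expression + metabolite matrices with planted couplings.

    Each coupled metabolite gets a latent coupling factor f.  Its value
    in the target condition is rho * f + sqrt(1 - rho^2) * noise_sd *
    N(0,1) (independent noise elsewhere and for uncoupled metabolites);
    latents are exponentiated to positive abundances.  The metabolite's
    primary driver gene tracks the factor exactly (attained pair
    Spearman = rho) and up to ``max_secondary`` further connected genes
    are co-regulated with attenuation lambda ~ U(secondary_range)
    (attained Spearman = lambda * rho) - emulating a co-expressed enzyme
    module around the metabolite.  Every gene drives at most one
    metabolite, so every recorded pair strength is exact.

    sign_policy: "metabolite" (one random sign shared by the
    metabolite's pairs), "role" (products +, substrates -) or "random"
    (independent per pair).  Coupled genes receive a variance
    multiplier on their expression.  The fraction per condition counts
    coupled *metabolites* among cytosolic metabolites with at least one
    connected gene.
    """
    fractions = dict(DEFAULT_COUPLING_FRACTIONS)
    if coupling_fraction_by_condition:
        fractions.update(coupling_fraction_by_condition)
    for c, f in fractions.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"coupling fraction for {c!r} outside [0, 1]")
    lo, hi = strength_range
    if not (0.0 < lo <= hi <= 1.0):
        raise ValueError("strength_range must lie in (0, 1]")

    rng = np.random.default_rng(seed)
    samples = ([f"N{i:04d}" for i in range(1, n_samples_per_condition + 1)]
               + [f"C{i:04d}" for i in range(1, n_samples_per_condition + 1)])
    condition = pd.Series(
        [NONCANCEROUS] * n_samples_per_condition + [CANCER] * n_samples_per_condition,
        index=samples, name="condition")
    n_s = len(samples)

    pairs = connected_gm_pairs(network, CYTOSOL)
    genes_of: dict[str, list] = {}
    for p in pairs:
        genes_of.setdefault(p.metabolite_id, []).append(p)
    eligible = sorted(genes_of)
    if pathway_hot is None:
        counts: dict[int, int] = {}
        for p in pairs:
            for rid in p.connecting_reaction_ids:
                pw = network.reactions[rid].pathway_id
                counts[pw] = counts.get(pw, 0) + 1
        pathway_hot = min(counts, key=lambda k: (-counts[k], k)) if counts else None
    hot_mets = sorted({
        p.metabolite_id for p in pairs
        if any(network.reactions[rid].pathway_id == pathway_hot
               for rid in p.connecting_reaction_ids)
    }) if pathway_hot is not None else []

    if sign_policy not in ("metabolite", "role", "random"):
        raise ValueError(f"unknown sign_policy {sign_policy!r}")

    # --- choose coupled metabolites, hot-pathway first --------------------
    plantings: list[dict] = []
    taken: set[str] = set()
    for cond in (CANCER, NONCANCEROUS, BOTH):
        frac = fractions.get(cond, 0.0)
        n_want = int(round(frac * len(eligible)))
        if n_want == 0:
            continue
        avail = [m for m in eligible if m not in taken]
        if n_want > len(avail):
            raise ValueError(
                f"requested {n_want} couplings for {cond!r} but only "
                f"{len(avail)} connected metabolites remain")
        hot_pool = [m for m in hot_mets if m not in taken]
        n_hot = min(int(round(pathway_bias * n_want)), len(hot_pool))
        chosen = list(rng.choice(hot_pool, size=n_hot, replace=False)) if n_hot else []
        rest_pool = [m for m in avail if m not in set(chosen)]
        chosen += list(rng.choice(rest_pool, size=n_want - len(chosen), replace=False))
        for m in sorted(chosen):
            taken.add(m)
            plantings.append({"met": m, "cond": cond})

    # --- assign driver genes, signs and strengths --------------------------
    coupled: list[CoupledPair] = []
    gene_latent: dict[str, tuple[str, float, int]] = {}  # gene -> (met, lambda, sign)
    used_genes: set[str] = set()
    for pl in plantings:
        m, cond = pl["met"], pl["cond"]
        rho = float(rng.uniform(lo, hi))
        # strengths are target Spearman; generation happens on the Gaussian
        # copula scale, where Pearson r = 2 sin(pi rho / 6) yields exactly
        # that population Spearman
        r_lat = 2.0 * math.sin(math.pi * rho / 6.0)
        s_met = int(rng.choice([1, -1]))
        options = [p for p in genes_of[m] if p.gene_id not in used_genes]
        if not options:        # every connected gene already drives another
            continue
        if sign_policy == "role":
            # a pure-role primary keeps the role-determined sign coherent
            pure = [p for p in options
                    if not _mixed_role(network, m, p.connecting_reaction_ids)]
            pool_opts = pure if pure else options
        else:
            pool_opts = options
        primary = pool_opts[int(rng.integers(len(pool_opts)))]
        rest = [p for p in options if p is not primary]
        n_sec = min(max_secondary, len(rest)) if secondary_range else 0
        sec_idx = sorted(rng.choice(len(rest), size=n_sec, replace=False)) \
            if n_sec else []
        members = [(primary, 1.0, True)] + [
            (rest[i], float(rng.uniform(*secondary_range)), False)
            for i in sec_idx]
        pl["r_lat"] = r_lat
        pl["members"] = []
        for pair, lam, is_primary in members:
            if sign_policy == "metabolite":
                s = s_met
            elif sign_policy == "role":
                s = _majority_role_sign(network, pair.gene_id, m,
                                        pair.connecting_reaction_ids)
            else:
                s = int(rng.choice([1, -1]))
            used_genes.add(pair.gene_id)
            gene_latent[pair.gene_id] = (m, lam, s)
            pl["members"].append(pair.gene_id)
            attained = rho if is_primary else \
                6.0 / math.pi * math.asin(lam * r_lat / 2.0)
            coupled.append(CoupledPair(pair.gene_id, m, cond, attained, s,
                                       primary=is_primary))
    plantings = [pl for pl in plantings if pl.get("members")]

    # --- expression --------------------------------------------------------
    gene_ids = sorted(network.genes)
    gpos = {g: i for i, g in enumerate(gene_ids)}
    mu = rng.uniform(4.0, 12.0, size=len(gene_ids))
    sigma = rng.uniform(0.2, 1.5, size=len(gene_ids))
    for g in gene_latent:
        sigma[gpos[g]] *= math.sqrt(variance_multiplier)
    factors = {pl["met"]: rng.standard_normal(n_s) for pl in plantings}
    eps = rng.standard_normal((len(gene_ids), n_s))
    for g, (m, lam, s) in gene_latent.items():
        i = gpos[g]
        eps[i] = s * (lam * factors[m] + math.sqrt(1.0 - lam ** 2) * eps[i])
    expression = pd.DataFrame(mu[:, None] + sigma[:, None] * eps,
                              index=gene_ids, columns=samples)

    # --- metabolites -------------------------------------------------------
    met_ids = sorted(network.metabolites)
    cond_mask = {
        NONCANCEROUS: (condition == NONCANCEROUS).to_numpy(),
        CANCER: (condition == CANCER).to_numpy(),
        BOTH: np.ones(n_s, dtype=bool),
    }
    by_met = {pl["met"]: pl for pl in plantings}
    alpha = rng.uniform(0.5, 2.5, size=len(met_ids))
    beta = rng.uniform(0.4, 0.8, size=len(met_ids))
    latent = np.empty((len(met_ids), n_s))
    for i, m in enumerate(met_ids):
        eta = rng.standard_normal(n_s)
        u = eta.copy()
        pl = by_met.get(m)
        if pl is not None:
            mask = cond_mask[pl["cond"]]
            r_lat = pl["r_lat"]
            u[mask] = (r_lat * factors[m][mask]
                       + math.sqrt(1.0 - r_lat ** 2) * noise_sd * eta[mask])
        latent[i] = u
    metabolites = pd.DataFrame(np.exp(alpha[:, None] + beta[:, None] * latent),
                               index=met_ids, columns=samples)

    # --- clinical anchors -------------------------------------------------
    cancer_coupled = sorted({cp.metabolite_id for cp in coupled
                             if cp.condition in (CANCER, BOTH)})
    pool = cancer_coupled if cancer_coupled else met_ids
    hazard_links: list[tuple[str, float]] = []
    if n_hazard_metabolites > 0:
        n_take = min(n_hazard_metabolites, len(pool))
        picked = rng.choice(pool, size=n_take, replace=False)
        hazard_links = [(str(m), float(hazard_log_hr)) for m in sorted(picked)]
    er_link = None
    if er_shift is not None:
        in_hazard = {m for m, _ in hazard_links}
        er_pool = [m for m in pool if m not in in_hazard] or met_ids
        er_link = (str(er_pool[int(rng.integers(len(er_pool)))]), float(er_shift))

    truth = SyntheticTruth(coupled, hazard_links, er_link, pathway_hot, seed)
    cohort = OmicsCohort(expression, metabolites, condition)
    return cohort, truth


# ---------------------------------------------------------------------------
# Clinical generation
# ---------------------------------------------------------------------------

def _log_zscore_rows(values: pd.DataFrame) -> pd.DataFrame:
    logged = np.log(values.where(values > 0))
    z = logged.sub(logged.mean(axis=1), axis=0)
    sd = logged.std(axis=1, ddof=1).replace(0.0, 1.0)
    return z.div(sd, axis=0).fillna(0.0)


def generate_clinical(
    cohort: OmicsCohort,
    truth: SyntheticTruth,
    baseline_hazard: float = 0.02,
    seed: int = 0,
    t_max: float | None = None,
) -> OmicsCohort:
    """Fill survival and ER columns from the planted clinical links.

    Survival times are exponential proportional hazards with linear
    predictor sum(coef * z(metabolite)) over the hazard links (z = per-
    metabolite z-score of log abundance); censoring is independent
    Uniform(0, t_max) with t_max defaulting to 3.2 / baseline_hazard,
    which yields roughly 30% censoring at linear predictor zero.  The
    ER-like label is Bernoulli with logit = shift * z(er metabolite).
    """
    rng = np.random.default_rng(seed)
    n = len(cohort.samples)
    z = _log_zscore_rows(cohort.metabolites)
    lp = np.zeros(n)
    for m, coef in truth.hazard_links:
        lp += coef * z.loc[m].to_numpy()
    rate = baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    if t_max is None:
        t_max = 3.2 / baseline_hazard
    t_cens = rng.uniform(0.0, t_max, size=n)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens

    if truth.er_link is not None:
        m, shift = truth.er_link
        p_pos = 1.0 / (1.0 + np.exp(-shift * z.loc[m].to_numpy()))
    else:
        p_pos = np.full(n, 0.5)
    er = rng.random(n) < p_pos

    return dataclasses.replace(
        cohort,
        survival_time=pd.Series(time, index=cohort.samples, name="survival_time"),
        event=pd.Series(event, index=cohort.samples, name="event"),
        er_status=pd.Series(er.astype(int), index=cohort.samples, name="er_status"),
    )


# ---------------------------------------------------------------------------
# Cohort I/O (TSV, shared sample axis)
# ---------------------------------------------------------------------------

def write_cohort(cohort: OmicsCohort, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    cohort.expression.to_csv(d / "expression.tsv", sep="\t")
    cohort.metabolites.to_csv(d / "metabolites.tsv", sep="\t")
    clinical = pd.DataFrame({"sample": cohort.samples,
                             "condition": cohort.condition.values})
    for col, series in (("survival_time", cohort.survival_time),
                        ("event", cohort.event),
                        ("er_status", cohort.er_status)):
        if series is not None:
            clinical[col] = series.values
    clinical.to_csv(d / "clinical.tsv", sep="\t", index=False)


def read_cohort(directory) -> OmicsCohort:
    d = Path(directory)
    expression = pd.read_csv(d / "expression.tsv", sep="\t", index_col=0)
    metabolites = pd.read_csv(d / "metabolites.tsv", sep="\t", index_col=0)
    clin = pd.read_csv(d / "clinical.tsv", sep="\t").set_index("sample")
    kw = {}
    if "survival_time" in clin.columns:
        kw = {"survival_time": clin["survival_time"],
              "event": clin["event"].astype(bool),
              "er_status": clin["er_status"].astype(int)}
    return OmicsCohort(expression, metabolites, clin["condition"], **kw)
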