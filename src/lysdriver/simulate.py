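"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the six inputs of the analysis — proteome +
modification-site table, somatic mutation table, domain intervals,
predictor/conservation annotations, patient survival, and the heterogeneous
protein/drug network — under the same structural assumptions the
statistical model makes: per-position mutation counts are Poisson with
region-specific rates drawn from Gamma priors, predictor calls are
Bernoulli with class-specific probabilities, conservation scores are
logit-shifted Beta variates, survival times are exponential with a
group-specific hazard, and the network plants direct high-weight edges
between chosen seed and target proteins.

Each generator uses its own RNG stream derived from ``config.seed`` plus a
fixed offset, so stages are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regions import AMINO_ACIDS, RegionPartition

MOD_TYPES = (
    "ubiquitination",
    "acetylation",
    "SUMOylation",
    "glycation",
    "malonylation",
    "methylation",
    "succinylation",
)

# per-type flanking preference planted around sites so that consensus-group
# clustering and PSSM width selection have signal to recover
_MOTIF_FLANK = {t: AMINO_ACIDS[i % 20] for i, t in enumerate(MOD_TYPES)}
_MOTIF_PROB = 0.6

_OFFSETS = dict(proteome=0, truth=1, mutations=2, annotations=3, network=4, survival=5)


@dataclass
class SimulationConfig:
    n_proteins: int = 60
    protein_length_range: tuple[int, int] = (200, 800)
    n_patients: int = 100
    mod_types: tuple[str, ...] = MOD_TYPES
    site_density: float = 1.5  # modification sites per 100 residues
    # Gamma(shape, rate) for (lambda1, lambda2); mean 0.1 mutations/position
    # matches the pooled per-position density of large tumor cohorts
    prior_params: tuple[float, float, float, float] = (1.0, 10.0, 1.0, 10.0)
    enriched_fraction: float = 0.2
    enrichment_ratio: float = 3.0
    predictor_del_prob: tuple[float, float] = (0.8, 0.3)  # (mod-related, other)
    conservation_shift: float = 1.0  # logit-scale shift for mod-related class
    hazard_ratio: float = 2.0  # mutated vs non-mutated group
    network_size: tuple[int, int] = (50, 10)
    cancer_types: tuple[str, ...] = ("PANCAN",)
    null_equal_rates: bool = False  # lambda1 == lambda2 per protein (null runs)
    seed: int = 42

    def validate(self) -> None:
        lo, hi = self.protein_length_range
        if min(self.n_proteins, self.n_patients, lo, hi) <= 0 or lo > hi:
            raise ValueError("counts must be positive and min length <= max length")
        if self.site_density < 0:
            raise ValueError("site_density must be >= 0")
        if min(self.prior_params) <= 0:
            raise ValueError("Gamma prior parameters must be positive")
        if not 0 <= self.enriched_fraction <= 1:
            raise ValueError("enriched_fraction must lie in [0, 1]")
        if self.enrichment_ratio <= 0:
            raise ValueError("enrichment_ratio must be positive")
        if not all(0 <= p <= 1 for p in self.predictor_del_prob):
            raise ValueError("predictor_del_prob entries must lie in [0, 1]")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        if min(self.network_size) < 1:
            raise ValueError("network_size entries must be >= 1")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(self.seed + _OFFSETS[stage])


@dataclass
class GroundTruth:
    """What the generators actually planted, keyed by protein id."""

    rates: pd.DataFrame  # protein_id, lambda1, lambda2, true_r, enriched
    mutation_classes: pd.DataFrame = field(default_factory=pd.DataFrame)
    patient_groups: pd.DataFrame = field(default_factory=pd.DataFrame)
    planted_edges: pd.DataFrame = field(default_factory=pd.DataFrame)


def simulate_proteome(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random proteome plus modification-site table.

    Sequences are uniform over the 20 residues; site positions are drawn at
    ``site_density`` per 100 residues, forced to lysine, assigned a
    modification type, and flanked (probabilistically) with that type's
    preferred residues so motifs are recoverable.
    """
    config.validate()
    rng = config.rng("proteome")
    lo, hi = config.protein_length_range
    prot_rows, site_rows = [], []
    for i in range(config.n_proteins):
        pid = f"P{i:04d}"
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(list(AMINO_ACIDS), size=length)
        n_sites = int(round(config.site_density / 100 * length))
        n_sites = min(n_sites, length)
        positions = np.sort(rng.choice(length, size=n_sites, replace=False)) + 1
        for pos in positions:
            mod = config.mod_types[int(rng.integers(len(config.mod_types)))]
            flank = _MOTIF_FLANK.get(mod, "A")
            for off in (-2, -1, 1, 2):
                j = pos - 1 + off
                if 0 <= j < length and rng.random() < _MOTIF_PROB:
                    seq[j] = flank
            site_rows.append(dict(protein_id=pid, position=int(pos), mod_type=mod))
        # force lysine last so a neighbouring site's flank cannot overwrite it
        seq[positions - 1] = "K"
        prot_rows.append(dict(protein_id=pid, length=length, sequence="".join(seq)))
    proteins = pd.DataFrame(prot_rows)
    sites = pd.DataFrame(site_rows, columns=["protein_id", "position", "mod_type"])
    if len(sites):
        seqs = dict(zip(proteins["protein_id"], proteins["sequence"]))
        h = 10
        windows = []
        for row in sites.itertuples(index=False):
            s = seqs[row.protein_id]
            lo_i, hi_i = row.position - 1 - h, row.position - 1 + h + 1
            win = (
                "-" * max(0, -lo_i)
                + s[max(lo_i, 0) : min(hi_i, len(s))]
                + "-" * max(0, hi_i - len(s))
            )
            windows.append(win)
        sites["window"] = windows
    else:
        sites["window"] = pd.Series(dtype=str)
    return proteins, sites


def make_ground_truth(config: SimulationConfig, protein_ids) -> GroundTruth:
    """Draw per-protein rates from the Gamma priors and plant enrichment.

    Background rates come from Gamma(alpha2, beta2).  A configured fraction
    of proteins is enriched with ``lambda1 = enrichment_ratio * lambda2``;
    the rest draw ``lambda1`` independently from Gamma(alpha1, beta1) (or
    copy ``lambda2`` exactly when ``null_equal_rates`` is set).  The
    enriched flag records whether the realized ratio exceeds one.
    """
    rng = config.rng("truth")
    a1, b1, a2, b2 = config.prior_params
    ids = list(protein_ids)
    lam2 = rng.gamma(a2, 1.0 / b2, size=len(ids))
    forced_mask = np.zeros(len(ids), dtype=bool)
    if config.null_equal_rates:
        lam1 = lam2.copy()
    else:
        lam1 = rng.gamma(a1, 1.0 / b1, size=len(ids))
        n_enriched = int(round(config.enriched_fraction * len(ids)))
        forced = rng.choice(len(ids), size=n_enriched, replace=False)
        lam1[forced] = config.enrichment_ratio * lam2[forced]
        forced_mask[forced] = True
    true_r = lam1 / lam2
    rates = pd.DataFrame(
        dict(
            protein_id=ids,
            lambda1=lam1,
            lambda2=lam2,
            true_r=true_r,
            enriched=true_r > 1,
            forced=forced_mask,
        )
    )
    return GroundTruth(rates=rates)


def simulate_mutations(
    proteome: pd.DataFrame,
    partitions: dict[str, RegionPartition],
    truth: GroundTruth,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Per-position Poisson mutation counts expanded to patient records.

    Motif positions mutate at the protein's ``lambda1``, background
    positions at ``lambda2``; each event is assigned a uniformly random
    patient and cancer type, a reference residue from the sequence and a
    random different alternate residue.  Mutation class (modification-
    related vs other) is recorded in ``truth.mutation_classes``.
    """
    config.validate()
    rng = config.rng("mutations")
    rates = truth.rates.set_index("protein_id")
    rows = []
    for prot in proteome.itertuples(index=False):
        part = partitions.get(prot.protein_id)
        if part is None:
            continue
        lam1 = float(rates.loc[prot.protein_id, "lambda1"])
        lam2 = float(rates.loc[prot.protein_id, "lambda2"])
        if lam1 < 0 or lam2 < 0:
            raise ValueError("mutation rates must be non-negative")
        for positions, lam, cls in (
            (part.mod_positions, lam1, "modification-related"),
            (part.bg_positions, lam2, "other"),
        ):
            if positions.size == 0 or lam == 0:
                continue
            counts = rng.poisson(lam, size=positions.size)
            hits = np.repeat(positions, counts)
            for pos in hits:
                ref = prot.sequence[pos - 1]
                alt = ref
                while alt == ref:
                    alt = AMINO_ACIDS[int(rng.integers(20))]
                rows.append(
                    dict(
                        sample_id=f"S{int(rng.integers(config.n_patients)):04d}",
                        cancer_type=config.cancer_types[
                            int(rng.integers(len(config.cancer_types)))
                        ],
                        protein_id=prot.protein_id,
                        position=int(pos),
                        ref_aa=ref,
                        alt_aa=alt,
                        variant_class="Missense_Mutation",
                        mutation_class=cls,
                    )
                )
    mutations = pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "cancer_type",
            "protein_id",
            "position",
            "ref_aa",
            "alt_aa",
            "variant_class",
            "mutation_class",
        ],
    )
    mutations.insert(0, "mutation_id", [f"M{i:06d}" for i in range(len(mutations))])
    truth.mutation_classes = mutations[["mutation_id", "mutation_class"]].copy()
    return mutations


def _logit_beta(rng, n, shift):
    x = rng.beta(2.0, 2.0, size=n)
    x = np.clip(x, 1e-9, 1 - 1e-9)
    return 1.0 / (1.0 + np.exp(-(np.log(x / (1 - x)) + shift)))


def simulate_annotations(
    proteome: pd.DataFrame,
    mutations: pd.DataFrame,
    config: SimulationConfig,
    truth: GroundTruth | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Domain intervals, predictor/conservation calls, survival, network.

    - domains: 1-3 random intervals per protein, merged to non-overlap;
    - predictors: five Bernoulli columns with class-specific success
      probability; conservation Beta-shaped on [0, 1], logit-shifted for
      modification-related mutations;
    - survival: exponential times with hazard scaled by ``hazard_ratio``
      for patients carrying a modification-related mutation, independent
      exponential censoring;
    - network: connected protein spanning tree plus extra edges, drug nodes
      attached to proteins only; a planted high-weight seed->target edge
      list is recorded in the ground truth when provided.
    """
    config.validate()
    rng = config.rng("annotations")

    dom_rows = []
    for prot in proteome.itertuples(index=False):
        for _ in range(int(rng.integers(1, 4))):
            span = int(rng.integers(20, max(21, prot.length // 3)))
            start = int(rng.integers(1, max(2, prot.length - span)))
            dom_rows.append(
                dict(
                    protein_id=prot.protein_id,
                    start=start,
                    end=min(start + span, prot.length),
                    domain_name=f"DOM{int(rng.integers(8)):02d}",
                )
            )
    domains = pd.DataFrame(dom_rows)

    p_mod, p_other = config.predictor_del_prob
    is_mod = (mutations["mutation_class"] == "modification-related").to_numpy()
    probs = np.where(is_mod, p_mod, p_other)
    pred = pd.DataFrame({"mutation_id": mutations["mutation_id"]})
    for col in ("sift", "pp2_hvar", "pp2_hdiv", "lrt", "fathmm"):
        pred[col] = rng.random(len(mutations)) < probs
    cons = np.empty(len(mutations))
    cons[is_mod] = _logit_beta(rng, int(is_mod.sum()), config.conservation_shift)
    cons[~is_mod] = _logit_beta(rng, int((~is_mod).sum()), 0.0)
    pred["conservation"] = cons
    pred["mutation_class"] = mutations["mutation_class"].to_numpy()

    srng = config.rng("survival")
    patients = [f"S{i:04d}" for i in range(config.n_patients)]
    mutated = set(
        mutations.loc[mutations["mutation_class"] == "modification-related", "sample_id"]
    )
    base_hazard = 1.0 / 1000.0  # baseline mean survival 1,000 days
    haz = np.array(
        [base_hazard * (config.hazard_ratio if p in mutated else 1.0) for p in patients]
    )
    times = srng.exponential(1.0 / haz)
    censor = srng.exponential(2000.0, size=len(patients))
    survival = pd.DataFrame(
        dict(
            patient_id=patients,
            time=np.minimum(times, censor).round(1) + 0.1,
            event=(times <= censor).astype(int),
            group=["mutated" if p in mutated else "non-mutated" for p in patients],
        )
    )
    if truth is not None:
        truth.patient_groups = survival[["patient_id", "group"]].copy()

    nrng = config.rng("network")
    n_prot, n_drug = config.network_size
    prot_nodes = [f"N{i:04d}" for i in range(n_prot)]
    drug_nodes = [f"D{i:03d}" for i in range(n_drug)]
    edge_rows = []
    for i in range(1, n_prot):
        j = int(nrng.integers(i))  # random spanning tree keeps the graph connected
        edge_rows.append(
            dict(
                source=prot_nodes[j],
                target=prot_nodes[i],
                weight=float(nrng.uniform(0.5, 1.5)),
                edge_kind="ppi",
            )
        )
    for _ in range(2 * n_prot):
        i, j = nrng.integers(n_prot, size=2)
        if i != j:
            edge_rows.append(
                dict(
                    source=prot_nodes[int(i)],
                    target=prot_nodes[int(j)],
                    weight=float(nrng.uniform(0.5, 1.5)),
                    edge_kind="ppi",
                )
            )
    for d in drug_nodes:
        for j in nrng.choice(n_prot, size=int(nrng.integers(1, 3)), replace=False):
            edge_rows.append(
                dict(
                    source=prot_nodes[int(j)],
                    target=d,
                    weight=float(nrng.uniform(0.5, 1.5)),
                    edge_kind="drug_target",
                )
            )
    edges = pd.DataFrame(edge_rows)
    return domains, pred, survival, edges


def plant_proximity(
    edges: pd.DataFrame,
    seed_node: str,
    target_node: str,
    weight: float = 25.0,
) -> pd.DataFrame:
    """Append a direct high-weight edge making ``target_node`` proximal to the seed."""
    extra = pd.DataFrame(
        [dict(source=seed_node, target=target_node, weight=weight, edge_kind="ppi")]
    )
    return pd.concat([edges, extra], ignore_index=True)


def simulate_all(config: SimulationConfig):
    """Convenience wrapper producing every table plus the ground truth.

    Region partitions used for mutation generation are built from the true
    site positions with the configured half-width floor (width 2), so the
    planted enrichment is defined over the same regions the pipeline will
    approximately recover.
    """
    from .regions import build_partition

    proteins, sites = simulate_proteome(config)
    partitions = {}
    for pid, grp in sites.groupby("protein_id"):
        length = int(proteins.loc[proteins["protein_id"] == pid, "length"].iloc[0])
        part = build_partition(pid, length, [(int(p), 2) for p in grp["position"]])
        if part is not None:
            partitions[pid] = part
    truth = make_ground_truth(config, sorted(partitions))
    mutations = simulate_mutations(proteins, partitions, truth, config)
    domains, pred, surv, edges = simulate_annotations(proteins, mutations, config, truth)
    return dict(
        proteins=proteins,
        sites=sites,
        partitions=partitions,
        truth=truth,
        mutations=mutations,
        domains=domains,
        predictors=pred,
        survival=surv,
        edges=edges,
    )
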