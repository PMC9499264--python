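"""Synthetic studies with the statistical structure the pipeline assumes.

Generates the three input tables of a complete greenhouse trial:

* growth traits — per treatment × replicate, Normal(mean, sd) truncated
  at zero by resampling; dry weights are drawn as fresh weight × a
  Beta-distributed dry fraction so DW ≤ FW holds by construction, and
  the dry-biomass percentage is derived, never drawn;
* OTU tables — Dirichlet-multinomial communities: per sample, taxon
  proportions are drawn from Dirichlet(concentration × profile) and
  counts from Multinomial(library_size, proportions), with
  phylum-labelled lineages and duplicate soil samples per treatment;
* Ct tables — a stable housekeeping gene plus target genes offset from
  it, with planted fold changes entering as −log2(FC) cycles so the
  2^−ΔΔCt stage recovers them exactly in the noise-free limit, and a
  detection ceiling reached by large gene offsets.

Each output table draws from its own random stream seeded from
(master seed, table name), so adding one table never perturbs the
others.  The packaged default configs mirror the shape of the
reference study: 12 wheat / 8 maize treatments with the published
trait means and SDs, six pots per treatment, duplicate soil samples,
14 leaf target genes at two timepoints (21 and 60 days after sowing).
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import datasets
from .io import LINEAGE_RANKS, TIMEPOINTS, OtuTable
from .treatments import study_labels

__all__ = ["SimConfig", "default_config", "simulate_traits",
           "simulate_otu_table", "simulate_ct_table", "simulate_study"]

#: Default bacterial phylum profile of the rhizosphere communities:
#: Proteobacteria dominant above 55%, Bacteroidetes around 11%, minor
#: phyla between 3 and 8%, remainder pooled.
DEFAULT_PHYLUM_PROFILE: tuple[tuple[str, float], ...] = (
    ("Proteobacteria", 0.56),
    ("Bacteroidetes", 0.11),
    ("Verrucomicrobia", 0.08),
    ("Actinobacteria", 0.07),
    ("Acidobacteria", 0.05),
    ("TM7", 0.04),
    ("Gemmatimonadetes", 0.03),
    ("Other", 0.06),
)

#: Default fungal (ITS) phylum profile: four phyla above 90% together.
FUNGAL_PHYLUM_PROFILE: tuple[tuple[str, float], ...] = (
    ("Ascomycota", 0.45),
    ("Basidiomycota", 0.25),
    ("Aphelidiomycota", 0.12),
    ("Chytridiomycota", 0.10),
    ("Other", 0.08),
)

#: 14-gene leaf expression panel (essential-pathway genes).
DEFAULT_GENES: tuple[str, ...] = (
    "pgd", "pgk", "pyrk", "P450", "nmt1", "cer1", "sdq2",
    "agpll1", "oy1", "psbp6", "fad1", "aceS3", "sm2", "chs",
)

#: Genes planted with strong induction (FC 4) in the top treatment at
#: 21 DAS in the default config.
DEFAULT_INDUCED_GENES: tuple[str, ...] = (
    "aceS3", "agpll1", "cer1", "fad1", "nmt1", "oy1", "pgk", "pyrk", "pgd",
)

HOUSEKEEPING_GENE = "18S"


@dataclass
class SimConfig:
    """Complete description of one synthetic study.

    ``planted_fc`` is nested gene → treatment → timepoint → fold
    change; unlisted combinations default to 1 (no change).
    ``trait_means``/``trait_sds`` map treatment → trait → value.
    """

    crop: str = "wheat"
    seed: int = 0
    treatments: tuple[str, ...] = ()
    n_replicates: int = 6
    trait_means: dict = field(default_factory=dict)
    trait_sds: dict = field(default_factory=dict)
    phylum_profile: tuple = DEFAULT_PHYLUM_PROFILE
    fungal_phylum_profile: tuple = ()
    dispersion: float = 200.0          # Dirichlet concentration
    library_size: int = 50_000
    n_otus_per_phylum: int = 5
    n_soil_samples: int = 2            # duplicate soil samples per treatment
    effect_multipliers: dict = field(default_factory=dict)  # treatment→phylum→×
    genes: tuple[str, ...] = DEFAULT_GENES
    planted_fc: dict = field(default_factory=dict)
    gene_offsets: dict = field(default_factory=dict)  # cycles above housekeeping
    hk_ct_mean: float = 15.0
    hk_ct_sd: float = 0.3
    tech_rep_sd: float = 0.15
    n_bio_reps: int = 2
    n_tech_reps: int = 3

    def __post_init__(self):
        self.treatments = tuple(self.treatments) or study_labels(self.crop)
        self.fungal_phylum_profile = (tuple(self.fungal_phylum_profile)
                                      or FUNGAL_PHYLUM_PROFILE)
        for profile in (self.phylum_profile, self.fungal_phylum_profile):
            props = np.array([p for _, p in profile], dtype=float)
            if abs(props.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"phylum proportions sum to {props.sum()}, not 1")
            if (props < 0).any():
                raise ValueError("negative phylum proportion")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if self.dispersion <= 0:
            raise ValueError("Dirichlet concentration must be positive")
        for tdict in self.trait_sds.values():
            for trait, sd in tdict.items():
                if sd < 0:
                    raise ValueError(f"negative sd for trait {trait!r}")
        for g in self.planted_fc.values():
            for t in g.values():
                for fc in t.values():
                    if fc <= 0:
                        raise ValueError("planted fold changes must be positive")
        if self.hk_ct_sd < 0 or self.tech_rep_sd < 0:
            raise ValueError("Ct noise SDs must be nonnegative")
        if not self.gene_offsets:
            # spread target genes 6–12 cycles above the housekeeping gene
            self.gene_offsets = {
                g: 6.0 + 6.0 * i / max(len(self.genes) - 1, 1)
                for i, g in enumerate(self.genes)}

    def fc(self, gene: str, treatment: str, timepoint: str) -> float:
        return (self.planted_fc.get(gene, {}).get(treatment, {})
                .get(timepoint, 1.0))

    def rng(self, table: str) -> np.random.Generator:
        """Independent stream per output table: seeded from
        (master seed, crc32(table name))."""
        return np.random.default_rng([self.seed, zlib.crc32(table.encode())])

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        for key in ("treatments", "genes"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        for key in ("phylum_profile", "fungal_phylum_profile"):
            if raw.get(key):
                raw[key] = tuple((name, float(p)) for name, p in raw[key])
        return cls(**raw)


def default_config(crop: str = "wheat", seed: int = 0) -> SimConfig:
    """Packaged study configuration: published trait means/SDs, the
    default phylum profile, and strong induction of nine genes in the
    Char_MC-C_AMF treatment at 21 DAS."""
    means = datasets.trait_means(crop)
    sds = datasets.trait_sds(crop)
    planted = {g: {"Char_MC-C_AMF": {"21DAS": 4.0}}
               for g in DEFAULT_INDUCED_GENES}
    return SimConfig(
        crop=crop, seed=seed,
        trait_means={t: means.loc[t].to_dict() for t in means.index},
        trait_sds={t: sds.loc[t].to_dict() for t in sds.index},
        planted_fc=planted,
    )


def _trunc_normal(rng, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal draws truncated at 0 by resampling (keeps the shape of the
    upper tail, unlike clipping)."""
    if sd == 0:
        return np.full(size, float(mean))
    out = rng.normal(mean, sd, size)
    for _ in range(1000):
        neg = out < 0
        if not neg.any():
            return out
        out[neg] = rng.normal(mean, sd, int(neg.sum()))
    return np.clip(out, 0, None)


def _dry_fraction(rng, f_mean: float, f_sd: float, size: int) -> np.ndarray:
    """Beta-distributed dry fraction with the requested mean and SD."""
    if f_sd == 0 or f_mean <= 0 or f_mean >= 1:
        return np.full(size, float(np.clip(f_mean, 0, 1)))
    var = min(f_sd ** 2, 0.99 * f_mean * (1 - f_mean))
    kappa = f_mean * (1 - f_mean) / var - 1
    return rng.beta(f_mean * kappa, (1 - f_mean) * kappa, size)


def simulate_traits(config: SimConfig) -> pd.DataFrame:
    """Tidy trait table: n_replicates pot-level draws per treatment."""
    rng = config.rng("traits")
    n = config.n_replicates
    rows = []
    for t in config.treatments:
        means = config.trait_means.get(t, {})
        sds = config.trait_sds.get(t, {})
        values: dict[str, np.ndarray] = {}
        for trait in ("root_length_cm", "shoot_length_cm", "spad"):
            values[trait] = _trunc_normal(rng, means.get(trait, 0.0),
                                          sds.get(trait, 0.0), n)
        for organ in ("root", "shoot"):
            fw = _trunc_normal(rng, means.get(f"{organ}_fw_g", 0.0),
                               sds.get(f"{organ}_fw_g", 0.0), n)
            fw_mean = means.get(f"{organ}_fw_g", 0.0)
            dw_mean = means.get(f"{organ}_dw_g", 0.0)
            dw_sd = sds.get(f"{organ}_dw_g", 0.0)
            f_mean = dw_mean / fw_mean if fw_mean > 0 else 0.0
            f_sd = dw_sd / fw_mean if fw_mean > 0 else 0.0
            frac = _dry_fraction(rng, f_mean, f_sd, n)
            dw = fw * frac
            values[f"{organ}_fw_g"] = fw
            values[f"{organ}_dw_g"] = dw
            with np.errstate(divide="ignore", invalid="ignore"):
                pct = np.where(fw > 0, 100.0 * dw / fw, 0.0)
            values[f"{organ}_dry_biomass_pct"] = pct
        for trait, vals in values.items():
            for r, v in enumerate(vals, start=1):
                rows.append((t, r, trait, float(v)))
    return pd.DataFrame(rows, columns=["treatment", "replicate", "trait",
                                       "value"])


def _taxon_profile(config: SimConfig, community: str = "16S"
                   ) -> tuple[pd.DataFrame, np.ndarray]:
    """OTU-level lineage table and baseline proportions.

    Each phylum is split over ``n_otus_per_phylum`` genus-level OTUs
    with harmonic weights (a deterministic rank-abundance shape), so
    OTU proportions sum exactly to the configured phylum proportion.
    """
    k = config.n_otus_per_phylum
    weights = 1.0 / np.arange(1, k + 1)
    weights /= weights.sum()
    profile = (config.phylum_profile if community == "16S"
               else config.fungal_phylum_profile)
    kingdom = "Bacteria" if community == "16S" else "Fungi"
    lineage_rows, props, ids = [], [], []
    for phylum, p in profile:
        for i in range(k):
            ids.append(f"OTU_{phylum}_{i + 1}")
            lineage_rows.append({
                "kingdom": kingdom, "phylum": phylum,
                "class": "unassigned", "order": "unassigned",
                "family": "unassigned", "genus": f"{phylum}_g{i + 1}",
            })
            props.append(p * weights[i])
    lineages = pd.DataFrame(lineage_rows, index=pd.Index(ids, name="otu_id"),
                            columns=list(LINEAGE_RANKS))
    return lineages, np.asarray(props)


def simulate_otu_table(config: SimConfig, community: str = "16S") -> OtuTable:
    """Dirichlet-multinomial community counts, duplicate samples per
    treatment.  ``community`` selects the bacterial ("16S") or fungal
    ("ITS") phylum profile and random stream."""
    if community not in ("16S", "ITS"):
        raise ValueError("community must be '16S' or 'ITS'")
    rng = config.rng("otus" if community == "16S" else "otus_its")
    lineages, base = _taxon_profile(config, community)
    phyla = lineages["phylum"].to_numpy()
    counts, meta = {}, []
    for t in config.treatments:
        profile = base.copy()
        for phylum, mult in config.effect_multipliers.get(t, {}).items():
            profile[phyla == phylum] *= mult
        profile = profile / profile.sum()
        for r in range(1, config.n_soil_samples + 1):
            alpha = config.dispersion * profile
            p = rng.dirichlet(alpha)
            sample_id = f"{t}-{r}"
            counts[sample_id] = rng.multinomial(config.library_size, p)
            meta.append({"sample_id": sample_id, "treatment": t,
                         "replicate": r})
    counts = pd.DataFrame(counts, index=lineages.index)
    sample_meta = pd.DataFrame(meta).set_index("sample_id")
    return OtuTable(counts=counts, lineages=lineages, sample_meta=sample_meta)


def simulate_ct_table(config: SimConfig) -> pd.DataFrame:
    """Tidy Ct records: housekeeping plus offset target genes.

    The planted fold change of gene g in treatment t enters the target
    Ct as −log2(FC) cycles relative to the same gene in any other
    treatment, so ΔΔCt against a calibrator with FC 1 recovers it
    exactly.  Values above the detection ceiling are emitted as-is;
    the reader marks them undetermined.
    """
    rng = config.rng("ct")
    rows = []
    for t in config.treatments:
        for tp in TIMEPOINTS:
            for b in range(1, config.n_bio_reps + 1):
                hk_base = rng.normal(config.hk_ct_mean, config.hk_ct_sd) \
                    if config.hk_ct_sd > 0 else config.hk_ct_mean
                for k in range(1, config.n_tech_reps + 1):
                    noise = rng.normal(0, config.tech_rep_sd) \
                        if config.tech_rep_sd > 0 else 0.0
                    rows.append((HOUSEKEEPING_GENE, t, tp, b, k,
                                 hk_base + noise))
                for g in config.genes:
                    base = (hk_base + config.gene_offsets[g]
                            - np.log2(config.fc(g, t, tp)))
                    for k in range(1, config.n_tech_reps + 1):
                        noise = rng.normal(0, config.tech_rep_sd) \
                            if config.tech_rep_sd > 0 else 0.0
                        rows.append((g, t, tp, b, k, base + noise))
    return pd.DataFrame(rows, columns=["gene", "treatment", "timepoint",
                                       "bio_rep", "tech_rep", "ct"])


def simulate_study(config: SimConfig):
    """All tables of one synthetic study: traits, 16S OTU counts,
    ITS OTU counts, Ct records."""
    return (simulate_traits(config), simulate_otu_table(config, "16S"),
            simulate_otu_table(config, "ITS"), simulate_ct_table(config))
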