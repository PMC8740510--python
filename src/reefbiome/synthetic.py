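"""Synthetic OTU tables with planted structure and a ground-truth record.

The generator emulates a 4-season x 4-area x 2-habitat x 3-replicate
design (96 samples) of compositional counts:

* a few dominant OTUs with fixed expected shares (stronger dominance in
  water than in sediment);
* a heavy-tailed lognormal background whose OTU ordering is shared between
  habitats but whose tail is heavier in water (water communities are more
  dominated, sediment communities more even and richer);
* planted correlated blocks per habitat: members share a per-sample latent
  factor z so within-block log-abundance correlation equals ``block_rho``;
* one (or more) hub OTUs whose blocks draw most of their latent variance
  from the hub's common factor, so the hub correlates strongly with every
  member of several blocks;
* seasonal OTUs whose expected abundance is multiplied by
  ``seasonal_effect`` in one flagged season;
* environmental factors that are linear combinations of block latents plus
  Gaussian noise.

Counts are drawn multinomially per sample at the stated depth (an optional
Dirichlet overdispersion is available).  Everything is deterministic given
the seed.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .tables import (AREAS, HABITATS, SEASONS, EnvMatrix, OtuTable,
                     SampleFrame, ValidationError)

__all__ = [
    "GeneratorParams",
    "SyntheticTruth",
    "generate_dataset",
    "truth_edge_set",
    "write_truth",
    "read_truth",
]

WATER_FACTORS = ["Temp", "DO", "Chla", "Dep", "pH", "Sal", "Trans", "Turb",
                 "TOC", "SPM", "POM", "COD", "NH4-N", "NO3-N", "NO2-N",
                 "SiO3", "PO4"]
SEDIMENT_FACTORS = ["Par", "BD", "WC", "OM", "MC", "Sal", "EC", "pH"]


@dataclass
class GeneratorParams:
    """Defaults define the study conditions emulated by this package."""

    n_otus: int = 2000
    depth: int = 50_000
    # planted correlated blocks
    n_blocks_per_habitat: int = 3
    block_size: int = 10
    block_rho: float = 0.9          # within-block log-abundance correlation
    block_share: float = 0.002      # expected home-habitat share per member
    # home/off expected-share ratio; sediment taxa resuspend into the water
    # column more than water taxa settle and persist in sediment
    off_habitat_factor_water: float = 8.0
    off_habitat_factor_sediment: float = 3.0
    # hub OTUs spanning several blocks (planted keystones)
    n_hubs: int = 1
    hub_span: int = 3               # blocks per hub
    hub_alpha: float = 0.45          # share of block latent variance from hub factor
    hub_rho: float = 0.98           # hub's own coupling to its common factor
    # antagonist: a water taxon tracking one water block and suppressed with
    # one sediment block (source of the networks' negative inter-module edges)
    n_antagonists: int = 1
    antagonist_loading: float = 0.5
    # the hub's common factor also drives the water seasonal OTUs weakly
    # (a generalist keystone tracks the community's seasonal driver), and
    # each water seasonal OTU tracks one water block's specific factor
    seasonal_hub_coupling: float = 0.35
    seasonal_block_coupling: float = 0.2
    # seasonal shifts
    n_seasonal_per_habitat: int = 8
    seasonal_effect: float = 2.0    # multiplicative, in the flagged season
    seasonal_share: float = 0.003
    # composition
    dominant_shares_water: tuple = (0.10, 0.07, 0.05)
    dominant_shares_sediment: tuple = (0.04, 0.03, 0.02)
    background_tail_water: float = 1.7   # lognormal sd of background weights
    background_tail_sediment: float = 1.5
    habitat_jitter_sd: float = 0.3  # independent per-habitat baseline jitter
    # per-sample noise
    log_noise_sd: float = 0.5
    depth_jitter_sd: float = 0.05
    dirichlet_concentration: float = None  # optional overdispersion
    # environment
    env_noise_sd: float = 0.5
    env_loading: float = 1.0

    def coupled_factors(self):
        """(habitat, factor, block) triples coupled at ``env_loading``."""
        water_blocks = [f"w{i}" for i in range(self.n_blocks_per_habitat)]
        sed_blocks = [f"s{i}" for i in range(self.n_blocks_per_habitat)]
        pairs = []
        for fac, blk in zip(["NO2-N", "Temp", "Trans"], water_blocks):
            pairs.append(("water", fac, blk))
        for fac, blk in zip(["MC", "EC", "OM"], sed_blocks):
            pairs.append(("sediment", fac, blk))
        return pairs


@dataclass
class SyntheticTruth:
    """Ground truth of the planted structure, for recovery tests."""

    seed: int
    module_membership: dict          # otu_id -> block id
    hub_ids: list
    hub_blocks: dict                 # hub otu_id -> list of block ids
    block_habitat: dict              # block id -> habitat
    seasonal_effects: dict           # (otu_id, season) -> multiplicative factor
    env_loadings: dict               # (factor, block id) -> coefficient
    antagonist_ids: list = field(default_factory=list)
    antagonist_links: dict = field(default_factory=dict)  # otu -> (pos blk, neg blk)
    habitat_profiles: dict = field(default_factory=dict)  # habitat -> {otu: log share}


def truth_edge_set(truth: SyntheticTruth) -> set:
    """All within-block pairs plus hub-to-member pairs (unordered)."""
    edges = set()
    by_block = {}
    for otu, blk in truth.module_membership.items():
        by_block.setdefault(blk, []).append(otu)
    for members in by_block.values():
        for a, b in itertools.combinations(sorted(members), 2):
            edges.add(frozenset((a, b)))
    for hub, blocks in truth.hub_blocks.items():
        for blk in blocks:
            for member in by_block.get(blk, []):
                edges.add(frozenset((hub, member)))
    return edges


def _phylum_pool(rng, n):
    phyla = ["Proteobacteria", "Cyanobacteria", "Actinobacteriota",
             "Desulfobacterota", "Acidobacteriota", "Chloroflexi",
             "Firmicutes", "Bacteroidota", "Myxococcota", "Gemmatimonadota",
             "Planctomycetota", "Verrucomicrobiota"]
    weights = np.array([0.25, 0.1, 0.1, 0.08, 0.08, 0.08,
                        0.07, 0.07, 0.05, 0.05, 0.04, 0.03])
    return rng.choice(phyla, size=n, p=weights / weights.sum())


def generate_dataset(params: GeneratorParams = None, seed: int = 0):
    """Generate (OtuTable, SampleFrame, {habitat: EnvMatrix}, SyntheticTruth)."""
    p = params or GeneratorParams()
    rng = np.random.default_rng(seed)

    n_structural = (len(p.dominant_shares_water)
                    + 2 * p.n_blocks_per_habitat * p.block_size
                    + p.n_hubs + p.n_antagonists
                    + 2 * p.n_seasonal_per_habitat)
    if p.n_otus < n_structural:
        raise ValidationError(
            f"n_otus={p.n_otus} smaller than planted structure ({n_structural})")
    if p.n_hubs and p.hub_span > p.n_blocks_per_habitat:
        raise ValidationError("hub_span exceeds the number of blocks per habitat")

    width = len(str(p.n_otus))
    otu_ids = [f"OTU{i + 1:0{width}d}" for i in range(p.n_otus)]

    # --- index layout -----------------------------------------------------
    cursor = 0
    dom_idx = list(range(cursor, cursor + len(p.dominant_shares_water)))
    cursor += len(dom_idx)
    blocks = {}
    block_habitat = {}
    for h, tag in (("water", "w"), ("sediment", "s")):
        for b in range(p.n_blocks_per_habitat):
            blk = f"{tag}{b}"
            blocks[blk] = list(range(cursor, cursor + p.block_size))
            block_habitat[blk] = h
            cursor += p.block_size
    hub_idx = list(range(cursor, cursor + p.n_hubs))
    cursor += p.n_hubs
    antagonist_idx = list(range(cursor, cursor + p.n_antagonists))
    cursor += p.n_antagonists
    seasonal_idx = {}
    for h in HABITATS:
        seasonal_idx[h] = list(range(cursor, cursor + p.n_seasonal_per_habitat))
        cursor += p.n_seasonal_per_habitat
    background_idx = list(range(cursor, p.n_otus))

    # --- baseline expected shares per habitat -----------------------------
    shares = {h: np.zeros(p.n_otus) for h in HABITATS}
    for h, dom in (("water", p.dominant_shares_water),
                   ("sediment", p.dominant_shares_sediment)):
        shares[h][dom_idx] = dom
    off_factor = {"water": p.off_habitat_factor_water,
                  "sediment": p.off_habitat_factor_sediment}
    for blk, members in blocks.items():
        home = block_habitat[blk]
        off = "sediment" if home == "water" else "water"
        shares[home][members] = p.block_share
        shares[off][members] = p.block_share / off_factor[home]
    for i in hub_idx:
        shares["water"][i] = p.block_share
        shares["sediment"][i] = p.block_share / off_factor["water"]
    for i in antagonist_idx:
        shares["water"][i] = p.block_share
        shares["sediment"][i] = p.block_share / off_factor["water"]
    for h in HABITATS:
        off = "sediment" if h == "water" else "water"
        shares[h][seasonal_idx[h]] = p.seasonal_share
        shares[off][seasonal_idx[h]] = p.seasonal_share / off_factor[h]

    # heavy-tailed background with a shared OTU ordering across habitats
    u = rng.normal(size=len(background_idx))
    jw = rng.normal(scale=p.habitat_jitter_sd, size=len(background_idx))
    js = rng.normal(scale=p.habitat_jitter_sd, size=len(background_idx))
    w_water = np.exp(p.background_tail_water * u + jw)
    w_sed = np.exp(p.background_tail_sediment * u + js)
    for h, w in (("water", w_water), ("sediment", w_sed)):
        mass = 1.0 - shares[h].sum()
        if mass <= 0:
            raise ValidationError("planted shares exceed total composition")
        shares[h][background_idx] = mass * w / w.sum()

    # --- design -----------------------------------------------------------
    rows = []
    for habitat in HABITATS:
        for season in SEASONS:
            for area in AREAS:
                for rep in (1, 2, 3):
                    sid = f"{habitat[0].upper()}{season[:3].upper()}_{area}_{rep}"
                    rows.append({"sample_id": sid, "habitat": habitat,
                                 "season": season, "area": area,
                                 "replicate": rep})
    design_df = pd.DataFrame(rows).set_index("sample_id")
    design = SampleFrame(design_df)
    sample_ids = design.sample_ids
    n_samples = len(sample_ids)
    habitats = design.frame["habitat"].to_numpy()
    seasons = design.frame["season"].to_numpy()

    # --- latent factors ---------------------------------------------------
    hub_factor = {hub: rng.normal(size=n_samples) for hub in hub_idx}
    hub_blocks_map = {}
    block_list = sorted(blocks)
    water_blocks = [b for b in block_list if block_habitat[b] == "water"]
    for k, hub in enumerate(hub_idx):
        hub_blocks_map[otu_ids[hub]] = water_blocks[:p.hub_span]
    z = {}
    block_specific = {}
    for blk in block_list:
        v = rng.normal(size=n_samples)
        block_specific[blk] = v
        owner = None
        for hub in hub_idx:
            if blk in hub_blocks_map.get(otu_ids[hub], []):
                owner = hub
                break
        if owner is not None:
            z[blk] = (np.sqrt(p.hub_alpha) * hub_factor[owner]
                      + np.sqrt(1.0 - p.hub_alpha) * v)
        else:
            z[blk] = v

    sed_blocks = [b for b in block_list if block_habitat[b] == "sediment"]
    antagonist_links = {}
    for k, ant in enumerate(antagonist_idx):
        antagonist_links[otu_ids[ant]] = (
            water_blocks[k % len(water_blocks)],
            sed_blocks[k % len(sed_blocks)])

    seasonal_effects = {}
    for h in HABITATS:
        for k, i in enumerate(seasonal_idx[h]):
            season = SEASONS[k % len(SEASONS)]
            seasonal_effects[(otu_ids[i], season)] = p.seasonal_effect

    # --- per-sample log abundances ----------------------------------------
    eps = rng.normal(size=(n_samples, p.n_otus))
    logab = np.empty((n_samples, p.n_otus))
    sqrho, sqnoise = np.sqrt(p.block_rho), np.sqrt(1.0 - p.block_rho)
    sqhub, sqhubn = np.sqrt(p.hub_rho), np.sqrt(1.0 - p.hub_rho)
    for s in range(n_samples):
        base = np.log(shares[habitats[s]])
        latent = eps[s].copy()
        for blk, members in blocks.items():
            latent[members] = sqrho * z[blk][s] + sqnoise * eps[s][members]
        for hub in hub_idx:
            latent[hub] = sqhub * hub_factor[hub][s] + sqhubn * eps[s][hub]
        for k, ant in enumerate(antagonist_idx):
            pos, neg = antagonist_links[otu_ids[ant]]
            la = p.antagonist_loading
            latent[ant] = (np.sqrt(la) * z[pos][s] - np.sqrt(la) * z[neg][s]
                           + np.sqrt(max(0.0, 1.0 - 2 * la)) * eps[s][ant])
        if hub_idx and p.seasonal_hub_coupling > 0:
            gu, gb = p.seasonal_hub_coupling, p.seasonal_block_coupling
            u0 = hub_factor[hub_idx[0]][s]
            for k, i in enumerate(seasonal_idx["water"]):
                vb = block_specific[water_blocks[k % len(water_blocks)]][s]
                latent[i] = (np.sqrt(gu) * u0 + np.sqrt(gb) * vb
                             + np.sqrt(max(0.0, 1.0 - gu - gb)) * eps[s][i])
        logab[s] = base + p.log_noise_sd * latent
    for (otu, season), factor in seasonal_effects.items():
        j = otu_ids.index(otu)
        logab[seasons == season, j] += np.log(factor)

    # --- counts -----------------------------------------------------------
    probs = np.exp(logab - logab.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    depth_jitter = rng.lognormal(mean=-0.5 * p.depth_jitter_sd**2,
                                 sigma=p.depth_jitter_sd, size=n_samples)
    depths = np.maximum(1, np.round(p.depth * depth_jitter)).astype(int)
    counts = np.empty((n_samples, p.n_otus), dtype=np.int64)
    for s in range(n_samples):
        ps = probs[s]
        if p.dirichlet_concentration is not None:
            ps = rng.dirichlet(ps * p.dirichlet_concentration)
        counts[s] = rng.multinomial(depths[s], ps)

    # --- taxonomy ----------------------------------------------------------
    phyla = _phylum_pool(rng, p.n_otus)
    taxonomy = {otu: f"k__Bacteria;p__{ph};c__;o__;f__;g__"
                for otu, ph in zip(otu_ids, phyla)}
    table = OtuTable(sample_ids, otu_ids, counts, taxonomy)

    # --- environmental factors ---------------------------------------------
    env_loadings = {}
    env = {}
    coupled = {(h, f): blk for h, f, blk in p.coupled_factors()}
    for h, factor_names in (("water", WATER_FACTORS),
                            ("sediment", SEDIMENT_FACTORS)):
        mask_h = habitats == h
        sids = [sid for sid, m in zip(sample_ids, mask_h) if m]
        vals = np.empty((len(sids), len(factor_names)))
        for f, fac in enumerate(factor_names):
            blk = coupled.get((h, fac))
            noise = rng.normal(size=len(sids))
            if blk is not None:
                vals[:, f] = (p.env_loading * z[blk][mask_h]
                              + p.env_noise_sd * noise)
                env_loadings[(fac, blk)] = p.env_loading
            else:
                vals[:, f] = noise
        env[h] = EnvMatrix(sids, list(factor_names), vals)

    truth = SyntheticTruth(
        seed=seed,
        module_membership={otu_ids[i]: blk
                           for blk, members in blocks.items() for i in members},
        hub_ids=[otu_ids[i] for i in hub_idx],
        hub_blocks=hub_blocks_map,
        antagonist_ids=[otu_ids[i] for i in antagonist_idx],
        antagonist_links=antagonist_links,
        block_habitat=block_habitat,
        seasonal_effects=seasonal_effects,
        env_loadings=env_loadings,
        habitat_profiles={h: {otu_ids[i]: float(np.log(shares[h][i]))
                              for i in range(p.n_otus)} for h in HABITATS},
    )
    return table, design, env, truth


# ---------------------------------------------------------------------------
# Truth serialization: flat TSV for per-OTU roles + JSON sidecar


def write_truth(truth: SyntheticTruth, tsv_path, json_path):
    roles = {}
    for otu, blk in truth.module_membership.items():
        roles.setdefault(otu, {})["block"] = blk
    for hub in truth.hub_ids:
        roles.setdefault(hub, {})["hub_blocks"] = ",".join(truth.hub_blocks[hub])
    for (otu, season), f in truth.seasonal_effects.items():
        roles.setdefault(otu, {})["seasonal"] = f"{season}:{f:g}"
    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write("otu_id\tblock\thub_blocks\tseasonal\n")
        for otu in sorted(roles):
            r = roles[otu]
            fh.write(f"{otu}\t{r.get('block', '')}\t{r.get('hub_blocks', '')}"
                     f"\t{r.get('seasonal', '')}\n")
    doc = {
        "seed": truth.seed,
        "hub_ids": truth.hub_ids,
        "hub_blocks": truth.hub_blocks,
        "block_habitat": truth.block_habitat,
        "antagonist_ids": truth.antagonist_ids,
        "antagonist_links": {k: list(v) for k, v in truth.antagonist_links.items()},
        "module_membership": truth.module_membership,
        "seasonal_effects": {f"{o}|{s}": v
                             for (o, s), v in truth.seasonal_effects.items()},
        "env_loadings": {f"{f}|{b}": v
                         for (f, b), v in truth.env_loadings.items()},
        "habitat_profiles": truth.habitat_profiles,
    }
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)


def read_truth(json_path) -> SyntheticTruth:
    with open(json_path, encoding="utf-8") as fh:
        doc = json.load(fh)
    return SyntheticTruth(
        seed=doc["seed"],
        module_membership=doc["module_membership"],
        hub_ids=doc["hub_ids"],
        hub_blocks=doc["hub_blocks"],
        block_habitat=doc["block_habitat"],
        seasonal_effects={
            (k.split("|")[0], k.split("|")[1]): v
            for k, v in doc["seasonal_effects"].items()},
        env_loadings={
            (k.split("|")[0], k.split("|")[1]): v
            for k, v in doc["env_loadings"].items()},
        antagonist_ids=doc.get("antagonist_ids", []),
        antagonist_links={k: tuple(v)
                          for k, v in doc.get("antagonist_links", {}).items()},
        habitat_profiles=doc.get("habitat_profiles", {}),
    )
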