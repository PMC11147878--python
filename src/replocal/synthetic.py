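"""Synthetic multi-subject word-reading datasets with planted geometry.

The generator emulates the study conditions the analyses assume: a cohort of
subjects reading a list of abstract and concrete words (each presented three
times), with designated cortical regions whose multivoxel patterns carry a
representational geometry *shared across subjects*.  Each planted region is
driven by low-rank stimulus scores F (standardized concreteness for a
semantic region; classical-MDS coordinates of the orthographic or
phonological edit-distance RDM for form regions; a shared random vector
otherwise) through voxel loadings drawn once and reused for every subject:

    beta(s, stim, v) = w * F(stim) . L(v)  +  nuisance_s(stim, v)  +  noise

Subject-specific nuisance latents mimic idiosyncratic but structured
activity (they inflate each subject's RDM without contributing to
across-subject fidelity), and i.i.d. Gaussian noise is added per
presentation.  All randomness flows from one seed through named child
streams, so identical configs give bit-identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import MaskVolume, SubjectBetaSet, VolumeGrid, centered_grid
from .rdm import RDM, property_rdm
from .stringdist import (
    load_phoneme_features,
    orthographic_edit_distance,
    pairwise_distance_matrix,
    phonological_edit_distance,
)

REGION_SOURCES = ("semantic", "phonological", "orthographic", "shared-random")

#: ARPABET phoneme -> candidate grapheme spellings; one is sampled per use,
#: mimicking the many-to-many sound-spelling mapping of English so that
#: orthographic and phonological distances covary without being collinear
_GRAPHEMES = {
    "P": ["p", "pp"], "B": ["b", "bb"], "T": ["t", "tt", "ed"],
    "D": ["d", "dd"], "K": ["k", "c", "ck", "ch"], "G": ["g", "gg", "gu"],
    "CH": ["ch", "tch"], "JH": ["j", "g", "dge"], "F": ["f", "ph", "ff"],
    "V": ["v", "ve"], "TH": ["th"], "DH": ["th"],
    "S": ["s", "c", "ss"], "Z": ["z", "s"], "SH": ["sh", "ti", "ci"],
    "ZH": ["s", "z"], "HH": ["h", "wh"], "M": ["m", "mm", "mb"],
    "N": ["n", "nn", "kn"], "NG": ["ng", "n"], "L": ["l", "ll"],
    "R": ["r", "rr", "wr"], "W": ["w", "u"], "Y": ["y", "i"],
    "IY": ["ee", "ea", "ie", "y"], "IH": ["i", "y"],
    "EY": ["ay", "ai", "a", "eigh"], "EH": ["e", "ea"],
    "AE": ["a"], "AA": ["o", "a"], "AO": ["aw", "augh", "o"],
    "OW": ["o", "ow", "oa"], "UH": ["oo", "u"], "UW": ["u", "oo", "ew"],
    "AH": ["u", "o", "a"], "ER": ["er", "ur", "ir"],
    "AY": ["ie", "igh", "y"], "AW": ["ow", "ou"], "OY": ["oy", "oi"],
}

# Table-of-stimuli summary statistics the property distributions emulate
CONCRETENESS_ABSTRACT = (2.45, 0.59)
CONCRETENESS_CONCRETE = (4.79, 0.19)
FREQUENCY_ABSTRACT = (6.20, 1.87)
FREQUENCY_CONCRETE = (6.03, 1.44)
IMAGEABILITY_CONCRETENESS_R = 0.87


def synth_stimuli(n_abstract: int = 128, n_concrete: int = 64,
                  seed: int = 0) -> pd.DataFrame:
    """Word-level stimulus table with abstract/concrete property structure.

    Concreteness is drawn from the two group distributions (abstract
    2.45 +/- 0.59, concrete 4.79 +/- 0.19, clipped to [1, 5]); log10 word
    frequency is group-matched; imageability correlates ~0.87 with
    concreteness.  Words are spelled from randomly generated pronounceable
    ARPABET transcriptions via a phoneme-to-grapheme map, so orthographic
    and phonological distances covary realistically.
    """
    if n_abstract + n_concrete < 2:
        raise ValueError("need at least 2 words in total")
    rng = np.random.default_rng(seed)
    feats = load_phoneme_features()
    consonants = feats.index[feats["class"] == "consonant"].to_numpy()
    vowels = feats.index[feats["class"] == "vowel"].to_numpy()

    rows = []
    n_total = n_abstract + n_concrete
    for i in range(n_total):
        group = "abstract" if i < n_abstract else "concrete"
        c_mu, c_sd = (CONCRETENESS_ABSTRACT if group == "abstract"
                      else CONCRETENESS_CONCRETE)
        f_mu, f_sd = (FREQUENCY_ABSTRACT if group == "abstract"
                      else FREQUENCY_CONCRETE)
        conc = float(np.clip(rng.normal(c_mu, c_sd), 1.0, 5.0))
        r = IMAGEABILITY_CONCRETENESS_R
        imag = float(np.clip(
            3.5 + 1.2 * (r * (conc - 3.5) / 1.1 + np.sqrt(1 - r**2) * rng.normal()),
            1.0, 7.0,
        ))
        freq = float(np.clip(rng.normal(f_mu, f_sd), 1.0, 12.0))
        n_syll = int(np.clip(round(rng.normal(2.5, 0.9)), 1, 5))
        phones = []
        for _ in range(n_syll):
            phones.append(str(rng.choice(consonants)))
            phones.append(str(rng.choice(vowels)))
            if rng.random() < 0.4:
                phones.append(str(rng.choice(consonants)))
        word = "".join(str(rng.choice(_GRAPHEMES[p])) for p in phones)
        wid = f"w{i:03d}"
        rows.append(dict(
            stimulus_id=wid, word_id=wid, word=word,
            transcription=" ".join(phones), group=group,
            concreteness=conc, imageability=imag, frequency=freq,
            length=len(word), syllables=n_syll,
        ))
    return pd.DataFrame(rows)


def presentation_table(word_table: pd.DataFrame, n_presentations: int = 3) -> pd.DataFrame:
    """Expand a word table to one row per presentation (run-major order)."""
    blocks = []
    for r in range(n_presentations):
        block = word_table.copy()
        block["stimulus_id"] = block["word_id"] + f"_p{r}"
        block["presentation"] = r
        blocks.append(block)
    return pd.concat(blocks, ignore_index=True)


@dataclass
class Region:
    """A planted region: voxel members, geometry source and effect size."""

    name: str
    member: np.ndarray  # indices into the in-mask vector
    source: str = "semantic"
    effect: float = 1.0

    def __post_init__(self):
        self.member = np.asarray(self.member, dtype=int)
        if self.source not in REGION_SOURCES:
            raise ValueError(
                f"region source must be one of {REGION_SOURCES}, got {self.source!r}"
            )
        if not np.isfinite(self.effect) or self.effect < 0:
            raise ValueError(f"effect size must be finite and >= 0, got {self.effect}")


def ball_region(mask: MaskVolume, center_ijk, radius_vox: float,
                name: str = "region", source: str = "semantic",
                effect: float = 1.0) -> Region:
    """Region of all in-mask voxels within ``radius_vox`` of a voxel center."""
    d = np.linalg.norm(mask.ijk - np.asarray(center_ijk, float), axis=1)
    member = np.flatnonzero(d <= radius_vox)
    if member.size == 0:
        raise ValueError(f"region {name!r} contains no in-mask voxels")
    return Region(name, member, source, effect)


@dataclass
class SynthConfig:
    """Full description of a synthetic multi-subject dataset."""

    mask: MaskVolume
    n_subjects: int = 12
    regions: list = field(default_factory=list)
    noise_sd: float = 0.5
    n_latent: int = 16
    latent_sd: float = 0.5
    n_presentations: int = 3
    n_mds_components: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        seen = np.zeros(self.mask.n_voxels, dtype=bool)
        for reg in self.regions:
            if reg.member.max(initial=-1) >= self.mask.n_voxels:
                raise ValueError(f"region {reg.name!r} exceeds the mask")
            if seen[reg.member].any():
                raise ValueError(f"region {reg.name!r} overlaps another region")
            seen[reg.member] = True


@dataclass
class SynthGroundTruth:
    """Planted-region labels and geometries for parameter-recovery tests."""

    region_labels: np.ndarray      # per in-mask voxel: 0 background, 1..K regions
    regions: dict                  # name -> Region
    planted_rdms: dict             # name -> word-level RDM of the planted scores
    config: SynthConfig


def classical_mds(D: np.ndarray, k: int) -> np.ndarray:
    """Classical (Torgerson) MDS embedding of a distance matrix, k components."""
    D = np.asarray(D, float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:k]
    w_pos = np.clip(w[order], 0.0, None)
    return V[:, order] * np.sqrt(w_pos)


def _standardize(X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(X.T).T.astype(float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd


def _region_scores(region: Region, table: pd.DataFrame, n_mds: int,
                   rng: np.random.Generator) -> np.ndarray:
    """(n_words, n_components) standardized stimulus scores for a region."""
    if region.source == "semantic":
        return _standardize(table["concreteness"].to_numpy())
    if region.source == "shared-random":
        return _standardize(rng.standard_normal(len(table)))
    if region.source == "orthographic":
        rdm = pairwise_distance_matrix(
            table["word"].tolist(), orthographic_edit_distance,
            labels=table["word_id"].to_numpy(),
        )
    else:  # phonological
        feats = load_phoneme_features()
        rdm = pairwise_distance_matrix(
            table["transcription"].tolist(),
            lambda a, b: phonological_edit_distance(a, b, feats),
            labels=table["word_id"].to_numpy(),
        )
    return _standardize(classical_mds(rdm.D, n_mds))


def synth_betas(config: SynthConfig, table: pd.DataFrame):
    """Generate per-subject presentation-level beta sets plus ground truth.

    Returns ``(betasets, pres_table, ground_truth)``; ``betasets`` rows are
    aligned with ``pres_table`` (identical order for every subject).
    """
    rng_root = np.random.SeedSequence(config.seed)
    ss_shared, ss_subjects = rng_root.spawn(2)
    rng_shared = np.random.default_rng(ss_shared)
    n_words = len(table)
    n_vox = config.mask.n_voxels
    pres = presentation_table(table, config.n_presentations)

    # shared signal: word x voxel, identical for every subject
    signal = np.zeros((n_words, n_vox))
    labels = np.zeros(n_vox, dtype=int)
    planted = {}
    for k, region in enumerate(config.regions, start=1):
        F = _region_scores(region, table, config.n_mds_components, rng_shared)
        L = rng_shared.standard_normal((F.shape[1], region.member.size))
        signal[:, region.member] += (
            region.effect * (F @ L) / np.sqrt(F.shape[1])
        )
        labels[region.member] = k
        if F.shape[1] == 1:
            planted[region.name] = property_rdm(
                F[:, 0], labels=table["word_id"].to_numpy()
            )
        else:
            diff = F[:, None, :] - F[None, :, :]
            planted[region.name] = RDM(
                table["word_id"].to_numpy(), np.sqrt((diff**2).sum(-1))
            )

    betasets = []
    subj_seeds = ss_subjects.spawn(config.n_subjects)
    for s in range(config.n_subjects):
        rng_s = np.random.default_rng(subj_seeds[s])
        G = rng_s.standard_normal((config.n_latent, n_words))
        M = rng_s.standard_normal((config.n_latent, n_vox))
        nuisance = (config.latent_sd / np.sqrt(max(config.n_latent, 1))) * (G.T @ M)
        word_mean = signal + nuisance
        reps = [
            word_mean + config.noise_sd * rng_s.standard_normal(word_mean.shape)
            for _ in range(config.n_presentations)
        ]
        beta = np.vstack(reps)  # run-major, matching presentation_table
        betasets.append(SubjectBetaSet(
            f"sub-{s:02d}", config.mask, beta,
            pres["stimulus_id"].to_numpy(),
        ))
    truth = SynthGroundTruth(labels, {r.name: r for r in config.regions},
                             planted, config)
    return betasets, pres, truth


def searchlight_footprint(mask: MaskVolume, member: np.ndarray,
                          radius_vox: float = 3.0) -> np.ndarray:
    """Detectable footprint of a planted region under a searchlight.

    A center-assigned searchlight statistic carries signal wherever the
    sphere intersects the region, so the ground truth a recovered map should
    be compared against is the region dilated by the searchlight radius
    (clipped to the mask).  Returns a boolean vector over in-mask voxels.
    """
    member = np.asarray(member)
    if member.dtype == bool:
        member = np.flatnonzero(member)
    ijk = mask.ijk
    region = ijk[member]
    out = np.zeros(mask.n_voxels, dtype=bool)
    for i, c in enumerate(ijk):
        if np.any(np.einsum("ij,ij->i", region - c, region - c) <= radius_vox**2):
            out[i] = True
    return out


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap coefficient of two boolean voxel sets."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return 2.0 * (a & b).sum() / denom if denom else float("nan")


# ---------------------------------------------------------------------------
# Canned fixtures
# ---------------------------------------------------------------------------

@dataclass
class FixtureBundle:
    config: SynthConfig
    word_table: pd.DataFrame
    pres_table: pd.DataFrame
    betasets: list
    ground_truth: SynthGroundTruth

    @property
    def mask(self) -> MaskVolume:
        return self.config.mask


def _ball_mask(grid: VolumeGrid, radius_vox: float) -> MaskVolume:
    center = (np.asarray(grid.dims) - 1) / 2.0
    idx = np.indices(grid.dims).reshape(3, -1).T
    d = np.linalg.norm(idx - center, axis=1)
    return MaskVolume(grid, (d <= radius_vox).reshape(grid.dims))


FIXTURE_SEEDS = {"tiny": 101, "demo": 202}


def make_fixture(size: str = "tiny", seed: int = None, out_dir=None) -> FixtureBundle:
    """Deterministic test datasets: ``tiny`` for unit tests, ``demo`` for
    end-to-end parameter-recovery runs.

    tiny: 4 subjects, 12^3 grid, 24 words, one planted semantic region.
    demo: 12 subjects, 24^3 grid, 96 words, a semantic region in the left
    hemisphere and a phonological region in the right.
    """
    if size not in FIXTURE_SEEDS:
        raise ValueError(f"unknown fixture size {size!r}")
    if seed is None:
        seed = FIXTURE_SEEDS[size]
    if size == "tiny":
        grid = centered_grid((12, 12, 12), 3.0)
        mask = _ball_mask(grid, 4.5)
        table = synth_stimuli(16, 8, seed=seed)
        center = (np.asarray(grid.dims) - 1) / 2.0
        regions = [ball_region(mask, center + [-2, 0, 0], 2.0,
                               "semantic", "semantic", 1.0)]
        config = SynthConfig(mask=mask, n_subjects=4, regions=regions,
                             noise_sd=0.5, seed=seed)
    elif size == "demo":
        grid = centered_grid((24, 24, 24), 3.0)
        mask = _ball_mask(grid, 9.5)
        table = synth_stimuli(64, 32, seed=seed)
        center = (np.asarray(grid.dims) - 1) / 2.0
        regions = [
            ball_region(mask, center + [-5, 1, 0], 4.2,
                        "semantic", "semantic", 1.0),
            ball_region(mask, center + [5, -1, 0], 3.6,
                        "phonological", "phonological", 1.0),
        ]
        config = SynthConfig(mask=mask, n_subjects=12, regions=regions,
                             noise_sd=0.5, seed=seed)
    else:
        raise ValueError(f"unknown fixture size {size!r}")
    betasets, pres, truth = synth_betas(config, table)
    bundle = FixtureBundle(config, table, pres, betasets, truth)
    if out_dir is not None:
        write_fixture(bundle, out_dir)
    return bundle


def write_fixture(bundle: FixtureBundle, out_dir) -> dict:
    """Write a fixture bundle to disk (NIfTI volumes, TSV tables, YAML truth)."""
    from pathlib import Path

    import yaml

    from .grid import write_beta_set, write_mask, write_stimulus_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"mask": "mask.nii.gz", "stimuli": "stimuli.tsv",
                "words": "words.tsv", "betas": {}}
    write_mask(bundle.mask, out / "mask.nii.gz")
    write_stimulus_table(bundle.pres_table, out / "stimuli.tsv")
    write_stimulus_table(bundle.word_table, out / "words.tsv")
    for b in bundle.betasets:
        fname = f"{b.subject_id}_betas.nii.gz"
        write_beta_set(b, out / fname)
        manifest["betas"][b.subject_id] = fname
    cfg = bundle.config
    truth = {
        "seed": int(cfg.seed),
        "n_subjects": int(cfg.n_subjects),
        "noise_sd": float(cfg.noise_sd),
        "n_latent": int(cfg.n_latent),
        "latent_sd": float(cfg.latent_sd),
        "regions": [
            {"name": r.name, "source": r.source, "effect": float(r.effect),
             "n_voxels": int(r.member.size),
             "member": [int(i) for i in r.member]}
            for r in cfg.regions
        ],
    }
    with open(out / "ground_truth.yaml", "w") as fh:
        yaml.safe_dump(truth, fh)
    manifest["ground_truth"] = "ground_truth.yaml"
    return manifest
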