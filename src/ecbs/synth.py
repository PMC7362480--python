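"""Synthetic chemogenomic universe with ground truth.

The generator emulates the statistical structure the binding-similarity
method assumes: an evolutionary hierarchy of targets (superfamilies split
into families, families into targets) in which evolutionarily related
targets bind molecules sharing latent substructure.  Each family carries a
random latent bit pattern — the binding determinant; a target's actives are
random fingerprints with the family pattern superimposed and then perturbed
by independent bit flips.

Crucially, every molecule — active or background — additionally carries the
bit pattern of one of a shared pool of *scaffolds*: large blocks of
structural bits unrelated to binding.  Scaffold bits dominate raw
structural similarity, so a background molecule sharing a scaffold with a
reference active looks structurally similar without binding (the
activity-cliff regime), while a true binder on an unseen scaffold looks
structurally dissimilar (scaffold hopping).  This is the failure mode of
purely structural similarity that motivates a learned binding similarity,
and it is what separates the two methods on this benchmark.

Active affinities are drawn log-normally,
truncated below the 100 nM activity threshold; a configurable fraction of
additional "promiscuous" records above 100 nM exercises the affinity
filter.  Dose–response curves are simulated from the same Hill model that
the fitting code assumes, with multiplicative noise.

Molecules are fingerprint-native (bit vectors, no SMILES): the learning
machinery is decoupled from chemistry parsing, which has its own
real-molecule fixtures.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .activity import DoseResponse, hill_poc
from .bench import InteractionRecord
from .chemreg import MoleculeSet, molecule_from_bits
from .evoann import AnnotationCatalog, catalog_from_records

SYNTH_SCHEME = "synthetic"
SYNTH_LEVELS = ("family", "superfamily")
FIXTURE_FORMAT_VERSION = 1


@dataclass
class UniverseConfig:
    """Study conditions for the synthetic universe (defaults are the
    conditions every test and the acceptance run use)."""

    n_superfamilies: int = 2
    families_per_superfamily: int = 2
    targets_per_family: int = 3
    fingerprint_length: int = 256
    latent_bits_per_family: int = 16
    actives_per_target: int = 15
    background_molecules: int = 400
    bit_noise_rate: float = 0.05
    base_density: float = 0.10
    n_scaffolds: int = 12
    scaffold_bits: int = 40
    affinity_lognormal_params: tuple[float, float] = (1.0, 0.7)  # log10 nM
    promiscuous_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_superfamilies", "families_per_superfamily",
                     "targets_per_family", "fingerprint_length",
                     "latent_bits_per_family", "actives_per_target",
                     "background_molecules"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 <= self.bit_noise_rate < 0.5):
            raise ValueError("bit_noise_rate must be in [0, 0.5)")
        n_fam = self.n_superfamilies * self.families_per_superfamily
        if self.latent_bits_per_family * n_fam > self.fingerprint_length:
            raise ValueError(
                f"fingerprint too short: {n_fam} families × "
                f"{self.latent_bits_per_family} latent bits > "
                f"{self.fingerprint_length} bits")
        n_latent = self.latent_bits_per_family * n_fam
        if self.scaffold_bits > self.fingerprint_length - n_latent:
            raise ValueError(
                f"fingerprint too short: scaffold patterns of "
                f"{self.scaffold_bits} bits do not fit beside {n_latent} "
                f"latent bits")


@dataclass
class GroundTruth:
    binding: dict[str, set[str]]            # molecule -> true binding targets
    target_path: dict[str, tuple[str, str]]  # target -> (family, superfamily)
    latent_bits: dict[str, list[int]]        # family -> latent bit indices
    scaffold: dict[str, int] = field(default_factory=dict)  # molecule -> scaffold


@dataclass
class Universe:
    config: UniverseConfig
    molecules: MoleculeSet
    catalog: AnnotationCatalog
    interactions: list[InteractionRecord]
    truth: GroundTruth

    def background_ids(self) -> list[str]:
        bound = set(self.truth.binding)
        return [m for m in self.molecules.ids() if m not in bound]


def _draw_affinity(rng: np.random.Generator, mu: float, sigma: float,
                   below_log10: float = 2.0) -> float:
    """Log10-normal nM affinity truncated below 10**below_log10 (rejection)."""
    for _ in range(1000):
        x = rng.normal(mu, sigma)
        if x < below_log10:
            return float(10.0 ** x)
    return float(10.0 ** (below_log10 - 0.1))  # pragma: no cover


def simulate_universe(cfg: UniverseConfig) -> Universe:
    """Generate targets, annotations, molecules and interaction records.

    Fully reproducible under ``cfg.seed``.  Latent bit blocks are disjoint
    across families, so with zero bit noise any within-family active pair
    shares its full latent pattern while cross-superfamily pairs share
    latent bits only by chance through the random base bits.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.fingerprint_length
    mu, sigma = cfg.affinity_lognormal_params

    ann_rows: list[tuple[str, str, str]] = []
    target_path: dict[str, tuple[str, str]] = {}
    latent: dict[str, list[int]] = {}
    # disjoint latent blocks assigned from a shuffled index pool
    all_bits = rng.permutation(L)
    cursor = 0
    targets_by_family: dict[str, list[str]] = {}
    for s in range(cfg.n_superfamilies):
        sf = f"SF{s}"
        for f in range(cfg.families_per_superfamily):
            fam = f"FAM{s}_{f}"
            bits = sorted(int(b) for b in
                          all_bits[cursor:cursor + cfg.latent_bits_per_family])
            cursor += cfg.latent_bits_per_family
            latent[fam] = bits
            fam_targets = []
            for t in range(cfg.targets_per_family):
                tid = f"T{s}_{f}_{t}"
                fam_targets.append(tid)
                target_path[tid] = (fam, sf)
                ann_rows.append((tid, "family", fam))
                ann_rows.append((tid, "superfamily", sf))
            targets_by_family[fam] = fam_targets
    catalog = catalog_from_records(ann_rows, levels=SYNTH_LEVELS)

    # scaffold patterns live on the non-latent bits so binding determinants
    # and structural scaffolds are disentangled in the ground truth
    non_latent = np.array(sorted(set(range(L)) - {b for bb in latent.values()
                                                  for b in bb}))
    scaffold_patterns = [
        non_latent[rng.choice(len(non_latent), size=cfg.scaffold_bits,
                              replace=False)]
        for _ in range(cfg.n_scaffolds)
    ]
    scaffold_of: dict[str, int] = {}

    def make_bits(mol_id: str, fam: str | None) -> np.ndarray:
        sc = int(rng.integers(cfg.n_scaffolds))
        scaffold_of[mol_id] = sc
        bits = (rng.random(L) < cfg.base_density).astype(np.uint8)
        bits[scaffold_patterns[sc]] = 1
        if fam is not None:
            bits[latent[fam]] = 1
        if cfg.bit_noise_rate > 0:
            flips = rng.random(L) < cfg.bit_noise_rate
            bits = bits ^ flips.astype(np.uint8)
        if bits.sum() == 0:  # pragma: no cover - vanishingly unlikely
            bits[int(rng.integers(L))] = 1
        return bits

    molecules = []
    interactions: list[InteractionRecord] = []
    binding: dict[str, set[str]] = {}
    all_targets = sorted(target_path)
    for tid in all_targets:
        fam, _sf = target_path[tid]
        for i in range(cfg.actives_per_target):
            mid = f"A_{tid}_{i}"
            molecules.append(molecule_from_bits(mid, make_bits(mid, fam),
                                                scheme=SYNTH_SCHEME))
            binding[mid] = {tid}
            atype = str(rng.choice(["Ki", "IC50", "Kd", "EC50"]))
            interactions.append(InteractionRecord(
                mid, tid, atype, _draw_affinity(rng, mu, sigma)))
            if rng.random() < cfg.promiscuous_fraction:
                # borderline promiscuous record: another target, >100 nM
                other = str(rng.choice([t for t in all_targets if t != tid]))
                weak = float(10.0 ** rng.uniform(2.0, 4.0))
                interactions.append(InteractionRecord(mid, other, "IC50", weak))

    for i in range(cfg.background_molecules):
        mid = f"BG{i}"
        molecules.append(molecule_from_bits(mid, make_bits(mid, None),
                                            scheme=SYNTH_SCHEME))

    truth = GroundTruth(binding=binding, target_path=target_path,
                        latent_bits=latent, scaffold=scaffold_of)
    return Universe(config=cfg, molecules=MoleculeSet(molecules, "synthetic"),
                    catalog=catalog, interactions=interactions, truth=truth)


def simulate_dose_response(kd_nM: float, h: float, doses, noise_sd: float = 0.0,
                           seed: int = 0, compound_id: str = "",
                           target_id: str = "") -> DoseResponse:
    """Hill-shaped POC curve with multiplicative Gaussian noise.

    POC(c) = 100 / (1 + (c/Kd)^h), then each point is multiplied by
    (1 + ε) with ε ~ N(0, noise_sd).  POC is 50 at c = Kd, tends to 100 as
    c → 0 and to 0 as c ≫ Kd.
    """
    if not kd_nM > 0:
        raise ValueError("kd_nM must be positive")
    doses = np.asarray(doses, dtype=float)
    if len(doses) < 4:
        raise ValueError("need at least 4 doses")
    rng = np.random.default_rng(seed)
    poc = hill_poc(doses, kd_nM, h)
    if noise_sd > 0:
        poc = poc * (1.0 + rng.normal(0.0, noise_sd, size=len(doses)))
    return DoseResponse(concentrations_nM=doses, responses_poc=poc,
                        compound_id=compound_id, target_id=target_id)


def _bits_to_string(bits: np.ndarray) -> str:
    return "".join(str(int(b)) for b in bits)


def export_fixtures(universe: Universe, out_dir: str | Path) -> None:
    """Write the universe as plain-text fixture files with a manifest.

    Layout: molecules.fp.csv (mol_id, bits), interactions.tsv,
    annotations.tsv, truth.json, manifest.json.  The manifest records the
    generating config and format version; loaders refuse a fixture
    directory without one.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "mol_id": universe.molecules.ids(),
        "bits": [_bits_to_string(m.fingerprints[SYNTH_SCHEME])
                 for m in universe.molecules],
    }).to_csv(out / "molecules.fp.csv", index=False)
    pd.DataFrame(
        [(r.mol_id, r.target_id, r.affinity_type, repr(r.value_nM))
         for r in universe.interactions],
        columns=["mol_id", "target_id", "affinity_type", "value_nM"],
    ).to_csv(out / "interactions.tsv", sep="\t", index=False)
    from .evoann import write_annotations
    write_annotations(universe.catalog, out / "annotations.tsv")
    truth = {
        "binding": {m: sorted(ts) for m, ts in universe.truth.binding.items()},
        "target_path": {t: list(p) for t, p in universe.truth.target_path.items()},
        "latent_bits": universe.truth.latent_bits,
        "scaffold": universe.truth.scaffold,
    }
    (out / "truth.json").write_text(json.dumps(truth, sort_keys=True, indent=1))
    manifest = {
        "format_version": FIXTURE_FORMAT_VERSION,
        "config": asdict(universe.config),
        "seed": universe.config.seed,
        "scheme": SYNTH_SCHEME,
        "levels": list(universe.catalog.levels),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))


def load_fixtures(fixture_dir: str | Path) -> Universe:
    """Load a fixture directory written by :func:`export_fixtures`.

    Refuses a directory without a manifest (provenance enforcement) and
    round-trips losslessly: loading an exported universe reproduces its
    molecules, catalog, interactions and ground truth exactly.
    """
    d = Path(fixture_dir)
    manifest_path = d / "manifest.json"
    if not manifest_path.exists():
        raise IOError(f"fixture directory {d} has no manifest.json; refusing "
                      f"to load an unprovenanced fixture")
    manifest = json.loads(manifest_path.read_text())
    if manifest.get("format_version") != FIXTURE_FORMAT_VERSION:
        raise IOError(f"unsupported fixture format {manifest.get('format_version')}")
    cfg = UniverseConfig(**{k: tuple(v) if isinstance(v, list) else v
                            for k, v in manifest["config"].items()})
    mols_df = pd.read_csv(d / "molecules.fp.csv", dtype=str)
    molecules = MoleculeSet(
        [molecule_from_bits(r.mol_id,
                            np.frombuffer(r.bits.encode(), dtype=np.uint8) - ord("0"),
                            scheme=SYNTH_SCHEME)
         for r in mols_df.itertuples(index=False)],
        provenance=str(d),
    )
    inter_df = pd.read_csv(d / "interactions.tsv", sep="\t", dtype=str)
    interactions = [
        InteractionRecord(r.mol_id, r.target_id, r.affinity_type, float(r.value_nM))
        for r in inter_df.itertuples(index=False)
    ]
    from .evoann import load_annotations
    catalog = load_annotations(d / "annotations.tsv",
                               levels=tuple(manifest["levels"]))
    truth_raw = json.loads((d / "truth.json").read_text())
    truth = GroundTruth(
        binding={m: set(ts) for m, ts in truth_raw["binding"].items()},
        target_path={t: tuple(p) for t, p in truth_raw["target_path"].items()},
        latent_bits={f: list(map(int, b))
                     for f, b in truth_raw["latent_bits"].items()},
        scaffold={m: int(s) for m, s in truth_raw.get("scaffold", {}).items()},
    )
    return Universe(config=cfg, molecules=molecules, catalog=catalog,
                    interactions=interactions, truth=truth)


def fixture_digest(fixture_dir: str | Path) -> str:
    """SHA-256 over the fixture files, for determinism checks."""
    d = Path(fixture_dir)
    h = hashlib.sha256()
    for name in sorted(p.name for p in d.iterdir() if p.is_file()):
        h.update(name.encode())
        h.update((d / name).read_bytes())
    return h.hexdigest()
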