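"""Synthetic two-domain bioactivity studies.

The generator emulates the statistical structure of a public/proprietary
pair of bioactivity sources for one target, so every pipeline stage can
be exercised and validated without external data:

* two domains with opposite class skews (the public-like domain
  majority-active, the proprietary-like domain majority-inactive);
* controllable chemical-space overlap (the fraction of molecular
  scaffolds the two domains share) and exact-compound identity overlap
  (shared compound keys, default 10%);
* replicate measurements with log-normal noise, a controllable fraction
  of them planted as threshold-straddling conflicts in both domains;
* assay-format structure: proprietary-like rows carry an explicit
  cell-based/cell-free tag, public-like rows carry assay-type codes and
  cell-line annotations from which the format has to be derived.

Molecules are built combinatorially by attaching two substituent
fragments to a scaffold template. Ground-truth potency follows a latent
model: log10 potency (micromolar) = base + pharmacophore effect (if an
activity-conferring fragment is present) + a per-scaffold offset +
Gaussian noise. Thresholding at 10 uM therefore yields labels that are
learnable from structure, with a scaffold-dependent component that makes
transfer across scaffold-disjoint domains genuinely harder. The
chemistry is deliberately modest: fixture scaffolds are chosen to be
mutually dissimilar at the 0.230 Tanimoto threshold so scaffold families
separate cleanly under Butina clustering; medicinal-chemistry fidelity
is not the point.

Ground truth is written to a separate table that no pipeline stage ever
reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .config import logger
from .io import DEFAULT_DIALECT, ActivityTableRow

# ---------------------------------------------------------------------------
# Fragment vocabulary
# ---------------------------------------------------------------------------

#: Scaffold templates with two attachment points. Each combines one or
#: two ring systems used (nearly) uniquely across the list, so scaffold
#: families are as mutually dissimilar as drug-like chemistry with a
#: shared substituent vocabulary allows. Domains draw contiguous slices
#: of this list (or of an explicit permutation).
SCAFFOLD_TEMPLATES: tuple[str, ...] = (
    "[*:1]c1ccc2cc([*:2])ccc2c1",                    # naphthalene
    "[*:1]c1ccc2[nH]c(C(=O)NC3CCC([*:2])CC3)cc2c1",  # indole-amide-cyclohexane
    "[*:1]c1ccc2oc(CN3CCOC([*:2])C3)cc2c1",          # benzofuran-CH2-morpholine
    "[*:1]c1cnc2cc(OCCN3CCC([*:2])C3)ccc2c1",        # quinoline-O-ethyl-pyrrolidine
    "[*:1]c1ccc2sc(C3CCOC([*:2])C3)cc2c1",           # benzothiophene-oxane
    "[*:1]c1ccc2nc(C3CCC([*:2])C3)[nH]c2c1",         # benzimidazole-cyclopentane
    "[*:1]c1csc(-c2ccc([*:2])o2)n1",                 # thiazole-furan
    "[*:1]C1CC2CCC1CC2c1cnc([*:2])cn1",              # bicyclooctane-pyrazine
    "[*:1]C1CCOC1Cc1cc([*:2])nn1C",                  # THF-CH2-N-methylpyrazole
    "[*:1]C1CCC2(CC1)OCC(Cc1ccc([*:2])nn1)O2",       # dioxaspiro-CH2-pyridazine
    "[*:1]C1CN(c2nnc([*:2])s2)CCO1",                 # morpholine-thiadiazole
    "[*:1]c1ccc(C(=O)N2CCC([*:2])CC2)nc1",           # pyridine-amide-piperidine
    "[*:1]C1CCc2ccc([*:2])cc2O1",                    # chromane
    "[*:1]C1CCC(NC(=O)c2cc([*:2])on2)CC1",           # cyclohexyl-amide-isoxazole
    "[*:1]c1ccc(CCc2nnc([*:2])o2)cc1",               # phenethyl-oxadiazole
    "[*:1]c1cc(C)nc(OC2CCC([*:2])CC2)n1",            # methylpyrimidine-O-cyclohexane
)

#: Substituent fragments (single attachment point).
SUBSTITUENTS: tuple[str, ...] = (
    "[*:0]C",            # methyl
    "[*:0]CC",           # ethyl
    "[*:0]F",
    "[*:0]Cl",
    "[*:0]O",            # hydroxyl
    "[*:0]OC",           # methoxy
    "[*:0]N",            # amino
    "[*:0]C#N",
    "[*:0]C(F)(F)F",
    "[*:0]C(C)=O",       # acetyl
    "[*:0]CCO",          # hydroxyethyl
    "[*:0]S(N)(=O)=O",   # sulfonamide (activity-conferring)
    "[*:0]C(=O)O",       # carboxylic acid (activity-conferring)
    "[*:0]NS(C)(=O)=O",  # methanesulfonamido (activity-conferring)
)

#: Substituents that carry the activity-conferring groups.
PHARM_SUBSTITUENT_IDS: tuple[int, ...] = (11, 12, 13)

#: SMARTS patterns whose presence confers activity in the latent model.
PHARMACOPHORE_SMARTS: tuple[str, ...] = (
    "S(=O)(=O)[NH2]",          # primary sulfonamide
    "C(=O)[OX2H1]",            # carboxylic acid
    "[NX3;H1]S(=O)(=O)[CH3]",  # methanesulfonamido
)

#: A designated fixture vocabulary whose two scaffold groups are
#: exhaustively verified to keep every cross-group product pair below
#: Tanimoto 0.230 (small substituents only). Used where a test needs
#: scaffold families that are strictly separable at that threshold.
FIXTURE_SCAFFOLD_PERMUTATION: tuple[int, ...] = (0, 1, 6, 7, 8, 10)
FIXTURE_SUBSTITUENT_IDS: tuple[int, ...] = (0, 2, 3, 4, 5, 7)

_PHARM_PATTERNS = [Chem.MolFromSmarts(s) for s in PHARMACOPHORE_SMARTS]


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for one synthetic two-domain target."""

    n_scaffolds: int = 6                 # scaffolds per domain
    substituents_per_scaffold: int = 196  # substituent pairs per scaffold
    n_per_domain: int = 500
    pharm_fraction: float = 0.42         # library fraction carrying a pharmacophore
    scaffold_overlap: float = 0.5        # fraction of scaffolds shared
    identity_overlap: float = 0.10       # fraction of exact shared compounds
    active_fraction_public: float = 0.8
    active_fraction_proprietary: float = 0.2
    replicate_fraction: float = 0.2      # compounds with a second measurement
    conflict_rate: float = 0.05          # replicated compounds forced to conflict
    measurement_noise_sd: float = 0.3    # log10 units
    cell_based_fraction_public: float = 0.5
    cell_based_fraction_proprietary: float = 0.5
    # latent potency model (log10 micromolar)
    base_log_potency: float = 1.8
    pharmacophore_effect: float = -2.5
    scaffold_effect_sd: float = 0.4
    latent_noise_sd: float = 0.5
    flip_effect_proprietary: bool = False
    format_flip_prob: float = 0.0        # label noise on one public format
    noisy_assay_format: str | None = None
    #: optional vocabulary restrictions (template ordering / substituent
    #: subset), e.g. the strictly separable fixture vocabulary
    scaffold_permutation: tuple[int, ...] | None = None
    substituent_ids: tuple[int, ...] | None = None
    target_id: str = "TGT1"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("scaffold_overlap", "identity_overlap",
                     "active_fraction_public", "active_fraction_proprietary",
                     "replicate_fraction", "conflict_rate", "pharm_fraction",
                     "cell_based_fraction_public",
                     "cell_based_fraction_proprietary", "format_flip_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_scaffolds < 2:
            raise ValueError("n_scaffolds must be >= 2")
        n_shared = round(self.scaffold_overlap * self.n_scaffolds)
        available = len(self.scaffold_permutation or SCAFFOLD_TEMPLATES)
        if 2 * self.n_scaffolds - n_shared > available:
            raise ValueError(
                "requested scaffold pools exceed the available template set"
            )
        if self.scaffold_permutation is not None:
            bad = [i for i in self.scaffold_permutation
                   if not 0 <= i < len(SCAFFOLD_TEMPLATES)]
            if bad:
                raise ValueError(f"invalid scaffold template ids {bad}")
        if self.substituent_ids is not None:
            bad = [i for i in self.substituent_ids
                   if not 0 <= i < len(SUBSTITUENTS)]
            if bad:
                raise ValueError(f"invalid substituent ids {bad}")


@dataclass(frozen=True)
class LibraryCompound:
    compound_key: str
    smiles: str
    scaffold_id: int
    has_pharmacophore: bool


@dataclass
class LatentActivity:
    """Decomposed ground-truth potency so domain variants share draws."""

    scaffold_offset: dict[int, float]
    compound_noise: dict[str, float]
    spec: GeneratorSpec

    def log_potency(self, compound: LibraryCompound, flip: bool = False) -> float:
        confers = compound.has_pharmacophore != flip  # XOR
        effect = self.spec.pharmacophore_effect if confers else 0.0
        return (
            self.spec.base_log_potency
            + effect
            + self.scaffold_offset[compound.scaffold_id]
            + self.compound_noise[compound.compound_key]
        )

    def is_active(self, compound: LibraryCompound, threshold_um: float = 10.0,
                  flip: bool = False) -> bool:
        return self.log_potency(compound, flip) <= np.log10(threshold_um)


@dataclass
class SyntheticStudy:
    spec: GeneratorSpec
    public_rows: list[ActivityTableRow]
    proprietary_rows: list[ActivityTableRow]
    ground_truth: pd.DataFrame


def _decorate(scaffold: str, sub1: str, sub2: str) -> str | None:
    """Attach two substituents to a scaffold template via molzip."""
    s = Chem.MolFromSmiles(scaffold)
    r1 = Chem.MolFromSmiles(sub1.replace("[*:0]", "[*:1]"))
    r2 = Chem.MolFromSmiles(sub2.replace("[*:0]", "[*:2]"))
    if s is None or r1 is None or r2 is None:
        return None
    try:
        mol = Chem.molzip(Chem.CombineMols(Chem.CombineMols(s, r1), r2))
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    smiles = Chem.MolToSmiles(mol)
    if "." in smiles or "*" in smiles:  # unzipped or dangling attachment
        return None
    return smiles


def _has_pharmacophore(smiles: str) -> bool:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return False
    return any(mol.HasSubstructMatch(p) for p in _PHARM_PATTERNS)


def generate_library(spec: GeneratorSpec) -> list[LibraryCompound]:
    """Build the combinatorial compound library over the needed scaffolds.

    Scaffold ids index into :data:`SCAFFOLD_TEMPLATES`; both domains draw
    from contiguous, partially overlapping id ranges (see
    :func:`domain_scaffold_pools`). Per scaffold,
    ``substituents_per_scaffold`` substituent pairs are sampled without
    replacement from the full combinatorial set, seeded by the spec.
    """
    rng = np.random.default_rng(_derive(spec.seed, 0))
    n_shared = round(spec.scaffold_overlap * spec.n_scaffolds)
    n_total = 2 * spec.n_scaffolds - n_shared
    template_order = list(spec.scaffold_permutation or range(len(SCAFFOLD_TEMPLATES)))
    sub_ids = list(spec.substituent_ids or range(len(SUBSTITUENTS)))
    subs = [SUBSTITUENTS[i] for i in sub_ids]
    pairs = [(i, j) for i in range(len(subs)) for j in range(len(subs))]
    # stratify pairs by pharmacophore content so the library's fraction of
    # activity-conferring compounds is controlled, not binomially noisy
    pharm_pairs = [
        p for p in pairs
        if sub_ids[p[0]] in PHARM_SUBSTITUENT_IDS
        or sub_ids[p[1]] in PHARM_SUBSTITUENT_IDS
    ]
    plain_pairs = [p for p in pairs if p not in set(pharm_pairs)]
    library: list[LibraryCompound] = []
    seen: set[str] = set()  # symmetric scaffolds make (a,b) == (b,a)
    counter = 0
    for sid in range(n_total):
        template = SCAFFOLD_TEMPLATES[template_order[sid]]
        k = min(spec.substituents_per_scaffold, len(pairs))
        k_pharm = min(round(spec.pharm_fraction * k), len(pharm_pairs))
        k_plain = min(k - k_pharm, len(plain_pairs))
        chosen = [
            pharm_pairs[int(c)]
            for c in rng.choice(len(pharm_pairs), size=k_pharm, replace=False)
        ] if k_pharm else []
        chosen += [
            plain_pairs[int(c)]
            for c in rng.choice(len(plain_pairs), size=k_plain, replace=False)
        ] if k_plain else []
        for i, j in chosen:
            smiles = _decorate(template, subs[i], subs[j])
            if smiles is None:
                logger.warning("invalid product for scaffold %d pair (%d,%d)",
                               sid, i, j)
                continue
            if smiles in seen:
                continue
            seen.add(smiles)
            library.append(
                LibraryCompound(
                    compound_key=f"CPD{counter:06d}",
                    smiles=smiles,
                    scaffold_id=sid,
                    has_pharmacophore=_has_pharmacophore(smiles),
                )
            )
            counter += 1
    return library


def _derive(seed: int, offset: int) -> int:
    return (seed * 1_000_003 + offset) % (2**31)


def assign_latent_activity(
    compounds: Sequence[LibraryCompound],
    spec: GeneratorSpec,
    seed: int | None = None,
) -> LatentActivity:
    """Draw the ground-truth potency components for a library."""
    rng = np.random.default_rng(_derive(seed if seed is not None else spec.seed, 1))
    scaffold_ids = sorted({c.scaffold_id for c in compounds})
    offsets = {
        sid: float(rng.normal(0.0, spec.scaffold_effect_sd)) for sid in scaffold_ids
    }
    noise = {
        c.compound_key: float(rng.normal(0.0, spec.latent_noise_sd))
        for c in compounds
    }
    return LatentActivity(scaffold_offset=offsets, compound_noise=noise, spec=spec)


def domain_scaffold_pools(spec: GeneratorSpec) -> tuple[set[int], set[int]]:
    """Scaffold-id pools for the two domains.

    The first ``n_shared`` ids are common; each domain then takes its own
    exclusive block.
    """
    n_shared = round(spec.scaffold_overlap * spec.n_scaffolds)
    n_excl = spec.n_scaffolds - n_shared
    shared = set(range(n_shared))
    public = shared | set(range(n_shared, n_shared + n_excl))
    proprietary = shared | set(range(n_shared + n_excl, n_shared + 2 * n_excl))
    return public, proprietary


def _sample_members(
    pool: list[LibraryCompound],
    latent: LatentActivity,
    n: int,
    active_fraction: float,
    rng: np.random.Generator,
    flip: bool,
    exclude: set[str] = frozenset(),
) -> list[LibraryCompound]:
    candidates = [c for c in pool if c.compound_key not in exclude]
    actives = [c for c in candidates if latent.is_active(c, flip=flip)]
    inactives = [c for c in candidates if not latent.is_active(c, flip=flip)]
    n_active = round(active_fraction * n)
    n_inactive = n - n_active
    if len(actives) < n_active:
        raise ValueError(
            f"library supplies only {len(actives)} actives; {n_active} requested"
        )
    if len(inactives) < n_inactive:
        raise ValueError(
            f"library supplies only {len(inactives)} inactives; "
            f"{n_inactive} requested"
        )
    pick_a = rng.choice(len(actives), size=n_active, replace=False)
    pick_i = rng.choice(len(inactives), size=n_inactive, replace=False)
    members = [actives[int(i)] for i in pick_a] + [inactives[int(i)] for i in pick_i]
    order = rng.permutation(len(members))
    return [members[int(i)] for i in order]


_CELL_NAMES = ("HEK293", "CHO-K1", "HeLa", "U2OS")


def _emit_rows(
    members: Sequence[LibraryCompound],
    latent: LatentActivity,
    spec: GeneratorSpec,
    domain: str,
    rng: np.random.Generator,
) -> list[ActivityTableRow]:
    flip = spec.flip_effect_proprietary and domain == "proprietary_like"
    cell_frac = (
        spec.cell_based_fraction_public
        if domain == "public_like"
        else spec.cell_based_fraction_proprietary
    )
    rows: list[ActivityTableRow] = []
    for comp in members:
        true_log = latent.log_potency(comp, flip=flip)
        replicated = rng.random() < spec.replicate_fraction
        conflicted = replicated and rng.random() < spec.conflict_rate
        if conflicted:
            # one replicate safely on each side of the 10 uM threshold
            measured = [1.0 - 0.3, 1.0 + 0.3]
        else:
            k = 2 if replicated else 1
            measured = list(true_log + rng.normal(0, spec.measurement_noise_sd, k))

        cell_based = rng.random() < cell_frac
        if domain == "public_like":
            fmt = "cell_based" if cell_based else "cell_free"
            if (
                spec.noisy_assay_format is not None
                and fmt == spec.noisy_assay_format
                and rng.random() < spec.format_flip_prob
            ):
                # mirror every measurement across the threshold: format-
                # dependent label noise for the mixing analyses
                measured = [2.0 - m for m in measured]
            assay_type = "B" if rng.random() < 0.9 else "F"
            cell_name = rng.choice(_CELL_NAMES) if cell_based else None
            assay_format = None  # public sources do not annotate the format
        else:
            assay_type = None
            cell_name = None
            assay_format = "cell_based" if cell_based else "cell_free"

        for m in measured:
            value_um = float(10.0 ** m)
            rows.append(
                ActivityTableRow(
                    compound_key=comp.compound_key,
                    structure=comp.smiles,
                    measurement_type="IC50" if rng.random() < 0.7 else "Ki",
                    value_um=value_um,
                    relation="=",
                    target_id=spec.target_id,
                    domain=domain,
                    assay_type=assay_type,
                    cell_name=None if cell_name is None else str(cell_name),
                    assay_format=assay_format,
                )
            )
    return rows


def sample_domains(
    library: Sequence[LibraryCompound],
    latent: LatentActivity,
    spec: GeneratorSpec,
) -> SyntheticStudy:
    """Draw the two domain tables and the ground-truth table.

    The public-like domain hits ``active_fraction_public`` exactly in
    ground truth (and the proprietary-like domain its own fraction);
    ``identity_overlap`` of the proprietary draw is replaced by compounds
    copied verbatim from the public draw (shared scaffolds only), so the
    shared-key count is exact.
    """
    rng = np.random.default_rng(_derive(spec.seed, 2))
    pool_pub, pool_prop = domain_scaffold_pools(spec)
    by_pool_pub = [c for c in library if c.scaffold_id in pool_pub]
    by_pool_prop = [c for c in library if c.scaffold_id in pool_prop]
    shared_ids = pool_pub & pool_prop

    flip = spec.flip_effect_proprietary
    public = _sample_members(
        by_pool_pub, latent, spec.n_per_domain, spec.active_fraction_public,
        rng, flip=False,
    )
    public_keys = {c.compound_key for c in public}
    proprietary = _sample_members(
        by_pool_prop, latent, spec.n_per_domain, spec.active_fraction_proprietary,
        rng, flip=flip, exclude=public_keys,
    )

    n_id = round(spec.identity_overlap * spec.n_per_domain)
    if n_id > 0:
        donors = [c for c in public if c.scaffold_id in shared_ids]
        if len(donors) < n_id:
            raise ValueError(
                f"identity overlap needs {n_id} shared-scaffold compounds; "
                f"the public draw has only {len(donors)}"
            )
        pick = rng.choice(len(donors), size=n_id, replace=False)
        injected = [donors[int(i)] for i in pick]
        # replace proprietary members of the same ground-truth label so the
        # class balance is preserved
        for comp in injected:
            lbl = latent.is_active(comp, flip=flip)
            for k, existing in enumerate(proprietary):
                if (
                    latent.is_active(existing, flip=flip) == lbl
                    and existing.compound_key not in public_keys
                    and existing.compound_key
                    not in {c.compound_key for c in injected}
                ):
                    proprietary[k] = comp
                    break
            else:
                raise ValueError("could not preserve class balance while "
                                 "injecting identity overlap")

    public_rows = _emit_rows(public, latent, spec, "public_like", rng)
    proprietary_rows = _emit_rows(proprietary, latent, spec, "proprietary_like", rng)

    truth_records = []
    for domain, members in (("public_like", public),
                            ("proprietary_like", proprietary)):
        dflip = flip and domain == "proprietary_like"
        for comp in members:
            truth_records.append(
                {
                    "compound_key": comp.compound_key,
                    "domain": domain,
                    "scaffold_id": comp.scaffold_id,
                    "has_pharmacophore": comp.has_pharmacophore,
                    "true_potency_um": 10.0 ** latent.log_potency(comp, flip=dflip),
                    "true_label": (
                        "active" if latent.is_active(comp, flip=dflip) else "inactive"
                    ),
                }
            )
    return SyntheticStudy(
        spec=spec,
        public_rows=public_rows,
        proprietary_rows=proprietary_rows,
        ground_truth=pd.DataFrame(truth_records),
    )


def generate_study(spec: GeneratorSpec) -> SyntheticStudy:
    """Library -> latent activity -> domain sampling, in one call."""
    library = generate_library(spec)
    latent = assign_latent_activity(library, spec)
    return sample_domains(library, latent, spec)


def rows_to_frame(rows: Sequence[ActivityTableRow]) -> pd.DataFrame:
    """Serialize typed rows into the default (ChEMBL-like) table dialect."""
    d = DEFAULT_DIALECT
    records = []
    for r in rows:
        # alternate units deterministically by value so round-trips are exact
        records.append(
            {
                d["compound_key"]: r.compound_key,
                d["structure"]: r.structure,
                d["measurement_type"]: r.measurement_type,
                d["value"]: repr(r.value_um * 1e3),
                d["units"]: "nM",
                d["relation"]: r.relation,
                d["target_id"]: r.target_id,
                d["domain"]: r.domain,
                d["assay_type"]: r.assay_type or "",
                d["cell_name"]: r.cell_name or "",
                d["assay_format"]: r.assay_format or "",
            }
        )
    return pd.DataFrame.from_records(records)


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write the two activity tables and the ground-truth table.

    Deterministic: identical spec and seed give byte-identical files.
    The ground-truth table is a separate file that pipeline stages never
    read.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "public": outdir / "public_activity.csv",
        "proprietary": outdir / "proprietary_activity.csv",
        "ground_truth": outdir / "ground_truth.csv",
    }
    rows_to_frame(study.public_rows).to_csv(paths["public"], index=False)
    rows_to_frame(study.proprietary_rows).to_csv(paths["proprietary"], index=False)
    study.ground_truth.to_csv(paths["ground_truth"], index=False, float_format="%.10g")
    return paths


def spec_with(spec: GeneratorSpec, **overrides) -> GeneratorSpec:
    """A copy of a spec with selected fields replaced."""
    return replace(spec, **overrides)
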