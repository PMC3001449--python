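"""Synthetic families and toy structure pairs with known ground truth.

Two generators back the test strategy of the whole package:

* **Table-level**: :func:`simulate_family` draws per-alignment
  ``(PNI, SNG, RMSD)`` triples from a bilinear law with configurable
  coefficients, PNI-SNG coupling (co-linearity) and Gaussian noise.  PNI
  and SNG are quantized through integer ``(N_iden, N_gap, N_algn)`` counts
  first, so that generated tables satisfy the same arithmetic invariants as
  tables computed from real alignments, and the RMSD law is applied to the
  quantized values — a noiseless scenario is recovered *exactly* by the
  regression.
* **Coordinate-level**: :func:`simulate_structure_pair` builds a toy
  C-alpha trace (3.8 A consecutive spacing), copies it, applies controlled
  substitutions, internal gap regions, isotropic Gaussian positional noise
  and a random rigid motion, and returns the true residue correspondence —
  so the statistics pipeline can be checked against exact bookkeeping.

The coupling parameter is the target Pearson correlation between PNI and
SNG, chosen so the implied variance inflation factor is
``1 / (1 - coupling^2)``.  The SNG mean rises linearly with PNI, reaching
``sng_rate`` at the top of the PNI range — mimicking the empirical pattern
that indels accumulate together with substitutions in diverging families.

All randomness flows from per-scenario integer seeds through
``numpy.random.default_rng``; scenario collections split seeds with
``numpy.random.SeedSequence.spawn`` so results are reproducible across
platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import ScenarioError
from .structio import DomainStructure, ResidueCorrespondence

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: fraction of sng_rate used as the total SNG standard deviation
_SNG_SD_FRACTION = 0.2

CA_SPACING = 3.8  # Angstrom between consecutive C-alpha positions


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

@dataclass
class FamilyScenario:
    """Generating law for one synthetic family's alignment table."""

    family_id: str
    n_pairs: int = 200
    b0: float = 0.5
    b1_true: float = 0.02  # SSS, Angstrom per PNI percent
    b2_true: float = 0.15  # SIDS, Angstrom per SNG unit
    noise_sd: float = 0.2
    pni_range: tuple[float, float] = (20.0, 90.0)
    pni_sng_coupling: float = 0.5  # target corr(PNI, SNG); VIF = 1/(1-c^2)
    sng_rate: float = 6.0  # expected SNG at the top of the PNI range
    disulfide_mean: float = 0.5
    seed: int = 0
    n_algn_range: tuple[int, int] = (100, 300)

    def validate(self) -> None:
        lo, hi = self.pni_range
        if not (0 <= lo < hi <= 100):
            raise ScenarioError(f"{self.family_id}: invalid pni_range {self.pni_range}")
        if self.noise_sd < 0:
            raise ScenarioError(f"{self.family_id}: negative noise_sd")
        if not 0 <= self.pni_sng_coupling < 1:
            raise ScenarioError(
                f"{self.family_id}: coupling {self.pni_sng_coupling} outside [0, 1)"
            )
        if self.b0 < 0:
            raise ScenarioError(
                f"{self.family_id}: b0={self.b0} < 0 would make the zero-truncation "
                "of RMSD bind; use a nonnegative intercept"
            )
        if self.sng_rate < 0 or self.disulfide_mean < 0:
            raise ScenarioError(f"{self.family_id}: negative rate")
        if self.n_pairs < 1:
            raise ScenarioError(f"{self.family_id}: n_pairs < 1")


@dataclass
class SimulatedFamily:
    """A generated family table together with its generating truth."""

    scenario: FamilyScenario
    stats: pd.DataFrame  # columns family_id, pni, sng, rmsd, n_algn, n_iden, n_gap, ...

    @property
    def truth(self) -> dict:
        return asdict(self.scenario)


def simulate_family(s: FamilyScenario) -> SimulatedFamily:
    """Draw one family's alignment-statistic table from its scenario.

    PNI is uniform on ``pni_range``; SNG has a linear-in-PNI mean reaching
    ``sng_rate`` at the range top, with total standard deviation
    ``0.2 * sng_rate`` partitioned between the PNI-shared and independent
    components so that corr(PNI, SNG) equals the coupling; both are
    quantized through integer counts; RMSD follows the bilinear law on the
    quantized predictors plus Gaussian noise, truncated at zero.
    """
    s.validate()
    rng = np.random.default_rng(s.seed)
    lo, hi = s.pni_range
    n = s.n_pairs

    n_algn = rng.integers(s.n_algn_range[0], s.n_algn_range[1] + 1, size=n)
    pni_cont = rng.uniform(lo, hi, size=n)
    n_iden = np.clip(np.rint(n_algn * (1 - pni_cont / 100.0)), 0, n_algn).astype(int)
    pni = 100.0 * (1.0 - n_iden / n_algn)

    sd_pni = (hi - lo) / math.sqrt(12.0)
    s_tot = _SNG_SD_FRACTION * s.sng_rate
    c1 = s.pni_sng_coupling * s_tot / sd_pni
    c0 = s.sng_rate - c1 * hi
    # Quantizing SNG through the integer gap count adds rounding noise with
    # variance (standard_length/N_algn)^2 / 12; fold it into the independent
    # component's budget so corr(PNI, SNG) of the emitted table equals the
    # scenario's coupling (infeasibly high couplings clamp the budget at 0).
    var_quant = float(np.mean((100.0 / n_algn) ** 2)) / 12.0
    eps_var = max(0.0, s_tot**2 * (1.0 - s.pni_sng_coupling**2) - var_quant)
    eps_sd = math.sqrt(eps_var)
    sng_cont = np.maximum(0.0, c0 + c1 * pni + rng.normal(0.0, eps_sd, size=n))
    n_gap = np.maximum(0, np.rint(sng_cont * n_algn / 100.0)).astype(int)
    sng = 100.0 * n_gap / n_algn

    rmsd = s.b0 + s.b1_true * pni + s.b2_true * sng
    if s.noise_sd > 0:
        rmsd = rmsd + rng.normal(0.0, s.noise_sd, size=n)
    rmsd = np.maximum(0.0, rmsd)

    # mean of two domains' integer disulfide counts
    avg_ss = 0.5 * (
        rng.poisson(s.disulfide_mean, size=n) + rng.poisson(s.disulfide_mean, size=n)
    )
    p_score = rng.uniform(4.0, 12.0, size=n)  # all accurate by construction

    stats = pd.DataFrame(
        {
            "family_id": s.family_id,
            "domain_a": [f"{s.family_id}_d{2*i}" for i in range(n)],
            "domain_b": [f"{s.family_id}_d{2*i+1}" for i in range(n)],
            "pni": pni,
            "sng": sng,
            "rmsd": rmsd,
            "n_algn": n_algn,
            "n_iden": n_iden,
            "n_gap": n_gap,
            "p_score": p_score,
            "avg_disulfide": avg_ss,
        }
    )
    return SimulatedFamily(scenario=s, stats=stats)


def simulate_cohort(scenarios: Sequence[FamilyScenario]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate every scenario; return the stacked stats table and the truth table."""
    if len(scenarios) == 0:
        raise ScenarioError("empty scenario list")
    ids = [s.family_id for s in scenarios]
    if len(set(ids)) != len(ids):
        raise ScenarioError("duplicate family_ids in scenario list")
    sims = [simulate_family(s) for s in scenarios]
    stats = pd.concat([sim.stats for sim in sims], ignore_index=True)
    truth = pd.DataFrame([sim.truth for sim in sims])
    return stats, truth


# ---------------------------------------------------------------------------
# canned cohorts
# ---------------------------------------------------------------------------

def benchmark_cohort(
    seed: int = 0,
    n_families: int = 73,
    n_disulfide_rich: int | None = None,
    sss_shrink: float = 0.5,
) -> list[FamilyScenario]:
    """A cohort emulating a real structure-family study's spread.

    Families differ in size (80-400 alignments), PNI range, coupling, SSS
    (0.015-0.045 A/percent before any disulfide effect), SIDS (0.08-0.30
    A/SNG-unit) and noise; ``n_disulfide_rich`` families carry 1.8-4.0 mean
    disulfide bonds and have their SSS multiplied by ``sss_shrink``,
    encoding the hypothesis that covalent cross-links constrain the
    structural response to substitutions but not to indels.
    """
    if n_disulfide_rich is None:
        # same rich:poor proportion (10:73) at any cohort size
        n_disulfide_rich = max(1, round(n_families * 10 / 73))
    if n_disulfide_rich >= n_families:
        raise ScenarioError(
            f"n_disulfide_rich={n_disulfide_rich} must be < n_families={n_families}"
        )
    root = np.random.default_rng(seed)
    child_seeds = np.random.SeedSequence(seed).spawn(n_families)
    rich = set(root.choice(n_families, size=n_disulfide_rich, replace=False).tolist())
    scenarios = []
    for i in range(n_families):
        b1 = root.uniform(0.015, 0.045)
        if i in rich:
            b1 *= sss_shrink
            ss_mean = root.uniform(1.8, 4.0)
        else:
            ss_mean = root.uniform(0.0, 1.0)
        lo = root.uniform(15, 35)
        hi = root.uniform(70, 95)
        scenarios.append(
            FamilyScenario(
                family_id=f"fam{i:03d}",
                n_pairs=int(root.integers(80, 401)),
                b0=root.uniform(0.3, 0.8),
                b1_true=b1,
                b2_true=root.uniform(0.08, 0.30),
                noise_sd=root.uniform(0.15, 0.30),
                pni_range=(lo, hi),
                pni_sng_coupling=root.uniform(0.3, 0.7),
                sng_rate=root.uniform(3.0, 9.0),
                disulfide_mean=ss_mean,
                seed=int(child_seeds[i].generate_state(1)[0] % (2**31)),
            )
        )
    return scenarios


def disulfide_effect_cohort(
    seed: int = 0,
    n_families: int = 52,
    n_rich: int = 10,
    b1_base: float = 0.03,
    b1_jitter: float = 0.005,
    effect: float = 0.5,
    n_pairs: int = 150,
) -> list[FamilyScenario]:
    """Homogeneous cohort isolating a disulfide effect on SSS.

    Every family shares the same design (size, PNI range, coupling, noise);
    SSS is ``Normal(b1_base, b1_jitter)`` per family, multiplied by
    ``1 - effect`` in the ``n_rich`` disulfide-rich families.  ``effect=0``
    gives the exact null for calibration studies.
    """
    root = np.random.default_rng(seed)
    child_seeds = np.random.SeedSequence(seed).spawn(n_families)
    scenarios = []
    for i in range(n_families):
        is_rich = i < n_rich
        b1 = max(1e-4, root.normal(b1_base, b1_jitter))
        if is_rich:
            b1 *= 1.0 - effect
        scenarios.append(
            FamilyScenario(
                family_id=f"eff{i:03d}",
                n_pairs=n_pairs,
                b0=0.5,
                b1_true=b1,
                b2_true=max(1e-4, root.normal(0.15, 0.03)),
                noise_sd=0.25,
                pni_range=(20.0, 90.0),
                pni_sng_coupling=0.5,
                sng_rate=6.0,
                disulfide_mean=2.5 if is_rich else 0.3,
                seed=int(child_seeds[i].generate_state(1)[0] % (2**31)),
            )
        )
    return scenarios


# ---------------------------------------------------------------------------
# coordinate-level generator
# ---------------------------------------------------------------------------

@dataclass
class StructurePairSpec:
    """Recipe for one toy structure pair with exact bookkeeping."""

    length: int = 100
    n_substitutions: int = 0
    gap_regions: list[tuple[str, int, int]] = field(default_factory=list)
    # each gap: (domain "A"|"B", start_position in A coordinates, run_length)
    perturbation_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.length < 3:
            raise ScenarioError("length must be >= 3")
        if self.perturbation_sd < 0:
            raise ScenarioError("negative perturbation_sd")
        occupied: set[int] = set()
        for dom, start, run in self.gap_regions:
            if dom not in ("A", "B"):
                raise ScenarioError(f"gap domain must be 'A' or 'B', got {dom!r}")
            if run < 1:
                raise ScenarioError("gap run_length must be >= 1")
            span = range(start, start + run) if dom == "A" else range(start, start + 1)
            if dom == "A":
                if start < 1 or start + run > self.length - 1:
                    raise ScenarioError(
                        f"A-gap ({start}, {run}) touches a terminus or exceeds length"
                    )
            else:
                if start < 1 or start > self.length - 1:
                    raise ScenarioError(f"B-gap insertion point {start} not internal")
            # require an aligned residue between gap regions so each stays
            # a distinct maximal run
            padded = set(range(min(span) - 1, max(span) + 2))
            if padded & occupied:
                raise ScenarioError("gap regions overlap or are adjacent")
            occupied |= set(span)


@dataclass
class SimulatedPair:
    domain_a: DomainStructure
    domain_b: DomainStructure
    correspondence: ResidueCorrespondence
    n_iden_true: int
    n_gap_true: int
    n_aligned_true: int


def simulate_structure_pair(spec: StructurePairSpec) -> SimulatedPair:
    """Build a toy domain pair realizing the spec exactly.

    Domain A is an extended C-alpha trace along x (3.8 A spacing) with a
    random sequence.  Domain B starts as a copy; residues covered by an
    ``A`` gap region are deleted from B, ``B`` gap regions insert extra
    residues into B, ``n_substitutions`` aligned positions get a different
    residue identity, coordinates of B are perturbed with isotropic
    Gaussian noise and mapped through a uniformly random proper rigid
    motion.  The returned correspondence is the true mapping; the true
    ``N_iden`` / ``N_gap`` counts are attached for oracle tests.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    L = spec.length

    seq_a = rng.choice(_AA, size=L)
    coords_a = np.zeros((L, 3))
    coords_a[:, 0] = CA_SPACING * np.arange(L)

    deleted = set()
    insertions: dict[int, int] = {}
    for dom, start, run in spec.gap_regions:
        if dom == "A":
            deleted |= set(range(start, start + run))
        else:
            insertions[start] = run

    aligned_positions = [p for p in range(L) if p not in deleted]
    if spec.n_substitutions > len(aligned_positions):
        raise ScenarioError(
            f"{spec.n_substitutions} substitutions exceed {len(aligned_positions)} "
            "aligned positions"
        )
    sub_at = set(
        rng.choice(aligned_positions, size=spec.n_substitutions, replace=False).tolist()
    )

    seq_b: list[str] = []
    coords_b: list[np.ndarray] = []
    pairs: list[tuple[int, int]] = []
    for p in range(L):
        if p in insertions:
            for j in range(insertions[p]):
                seq_b.append(str(rng.choice(_AA)))
                # offset inserted residues off the backbone line
                coords_b.append(coords_a[p] + np.array([0.0, CA_SPACING * (j + 1), 0.0]))
        if p in deleted:
            continue
        aa = str(seq_a[p])
        if p in sub_at:
            aa = str(rng.choice(_AA[_AA != aa]))
        pairs.append((p, len(seq_b)))
        seq_b.append(aa)
        coords_b.append(coords_a[p].copy())

    coords_b = np.asarray(coords_b)
    if spec.perturbation_sd > 0:
        coords_b = coords_b + rng.normal(0.0, spec.perturbation_sd, coords_b.shape)
    rot = Rotation.random(rng=rng)
    translation = rng.uniform(-20.0, 20.0, size=3)
    coords_b = rot.apply(coords_b) + translation

    dom_a = DomainStructure(
        domain_id="simA",
        residues=[(i + 1, "A", str(aa)) for i, aa in enumerate(seq_a)],
        ca_coords=coords_a,
    )
    dom_b = DomainStructure(
        domain_id="simB",
        residues=[(i + 1, "B", aa) for i, aa in enumerate(seq_b)],
        ca_coords=coords_b,
    )
    corr = ResidueCorrespondence("simA", "simB", pairs)
    return SimulatedPair(
        domain_a=dom_a,
        domain_b=dom_b,
        correspondence=corr,
        n_iden_true=len(pairs) - spec.n_substitutions,
        n_gap_true=len(spec.gap_regions),
        n_aligned_true=len(pairs),
    )
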