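"""Synthetic barcoded reporter-screen data.

Emulates the statistical structure of a pooled GPCR deep-mutational-scanning
experiment: a segmented oligo library where each designed variant is tagged
by ~10 random 15-nt barcodes, oligo synthesis errors (single-base deletions),
cross-segment barcode chimeras, within-segment barcode collisions, per-base
sequencing errors, and RNA-seq style count tables in which a barcode's reads
are proportional to its cellular abundance times reporter induction, with
negative-binomial noise.

Reporter induction follows a Hill dose-response scaled by the variant's true
activity ``a``:

    f(a, dose) = basal + span * a * dose^h / (EC50^h + dose^h)

so the vehicle condition (dose 0) is activity-independent and saturating
agonist reads out ``a`` nearly linearly. Forskolin bypasses the receptor and
induces maximally, so forskolin counts measure cellular abundance alone.
Frameshift entries carry a floor activity (default 0.15).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .design import ReceptorDesign, Variant

BARCODE_LEN = 15
BASES = np.array(list("ACGT"))

#: screen conditions and agonist doses (nM); forskolin is the abundance control
DEFAULT_DOSES: dict[str, float] = {
    "vehicle": 0.0,
    "EC50": 150.0,
    "EC100": 625.0,
    "Emax": 5000.0,
}

CONDITIONS: tuple[str, ...] = ("forskolin", "vehicle", "EC50", "EC100", "Emax")


@dataclass
class SimulationConfig:
    """Knobs of the simulated screen; defaults are the study conditions."""

    barcodes_per_variant: int = 10  # Poisson mean, median 10
    deletion_rate: float = 0.10  # oligos carrying a 1-nt deletion
    chimera_rate: float = 0.02  # cross-segment barcode contamination
    collision_rate: float = 0.02  # within-segment two-variant barcodes
    synonymous_rate: float = 0.02  # wild-type-protein control barcodes
    seq_error_rate: float = 0.001  # per-base substitution rate in reads
    reads_per_barcode: float = 20.0  # Poisson mean, mapping run
    depth: float = 2e6  # reads per count-table column
    nb_dispersion: float = 0.1  # NB: var = m + alpha m^2
    abundance_sigma: float = 0.5  # lognormal sigma of cell abundance
    hill_ec50: float = 150.0  # nM
    hill_slope: float = 1.0
    basal: float = 0.05
    span: float = 1.0
    frameshift_floor: float = 0.15  # frameshift activity, x WT span
    n_replicates: int = 2
    doses: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DOSES))
    seed: int = 0

    def validate(self) -> None:
        for name in ("deletion_rate", "chimera_rate", "collision_rate",
                     "synonymous_rate", "seq_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("reads_per_barcode", "depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be nonnegative")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def hill_response(activity, dose: float, config: SimulationConfig):
    """Reporter induction f(a, dose) for scalar or array activity."""
    d, h = float(dose), config.hill_slope
    occ = 0.0 if d == 0 else d**h / (config.hill_ec50**h + d**h)
    return config.basal + config.span * np.asarray(activity, dtype=float) * occ


def _random_barcodes(n: int, rng: np.random.Generator) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        draw = rng.integers(0, 4, size=(n - len(out), BARCODE_LEN))
        for row in draw:
            bc = "".join(BASES[row])
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
    return out


def _draw_true_activity(n: int, rng: np.random.Generator) -> np.ndarray:
    """Variant activities: WT-like mode, a loss-of-function tail, some gain."""
    kind = rng.choice(3, size=n, p=[0.6, 0.3, 0.1])
    a = np.empty(n)
    a[kind == 0] = np.clip(rng.normal(1.0, 0.15, (kind == 0).sum()), 0.05, None)
    a[kind == 1] = rng.uniform(0.05, 0.7, (kind == 1).sum())
    a[kind == 2] = rng.uniform(1.2, 2.0, (kind == 2).sum())
    return a


def _delete_one_base(seq: str, rng: np.random.Generator) -> str:
    i = int(rng.integers(len(seq)))
    return seq[:i] + seq[i + 1 :]


def _add_read_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        cur = arr[i].decode()
        alts = [b for b in "ACGT" if b != cur]
        arr[i] = alts[int(rng.integers(3))].encode()
    return arr.tobytes().decode()


def simulate_library(design: ReceptorDesign, config: SimulationConfig) -> pd.DataFrame:
    """Ground-truth barcode manifest.

    One row per barcode: ``barcode``, ``truth_class`` in {missense,
    frameshift, synonymous, chimera, collision}, ``variant`` (label or
    specification), ``position``/``wt_aa``/``mut_aa`` for missense,
    ``true_activity`` (intrinsic activity a), plus the inserted segment
    sequence(s) used when emitting reads (columns ``insert_seq``,
    ``insert_seq2``, ``minor_frac``).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    variants = design.variants
    n_var = len(variants)
    true_a = _draw_true_activity(n_var, rng)
    n_bc_per_var = np.maximum(1, rng.poisson(config.barcodes_per_variant, n_var))

    rows: list[dict] = []
    for vi, v in enumerate(variants):
        seg = design.segment_of(v.position)
        var_seq = design.variant_seq(v)
        for _ in range(int(n_bc_per_var[vi])):
            u = rng.random()
            row = {
                "truth_class": "missense",
                "variant": v.label,
                "position": v.position,
                "wt_aa": v.wt_aa,
                "mut_aa": v.mut_aa,
                "segment": seg,
                "true_activity": true_a[vi],
                "insert_seq": var_seq,
                "insert_seq2": "",
                "minor_frac": 0.0,
            }
            if u < config.deletion_rate:
                # synthesis error: the oligo itself carries a 1-nt deletion
                row.update(
                    truth_class="frameshift",
                    variant=f"fs({v.label})",
                    true_activity=config.frameshift_floor,
                    insert_seq=_delete_one_base(var_seq, rng),
                )
            elif u < config.deletion_rate + config.chimera_rate and len(design.segments) > 1:
                other_segs = [s for s in range(len(design.segments)) if s != seg]
                s2 = other_segs[int(rng.integers(len(other_segs)))]
                row.update(
                    truth_class="chimera",
                    variant=f"chimera({v.label},seg{s2})",
                    insert_seq2=design.segment_seq(s2),
                    minor_frac=rng.uniform(0.2, 0.5),
                )
            elif u < config.deletion_rate + config.chimera_rate + config.collision_rate:
                same_seg = [w for w in variants if design.segment_of(w.position) == seg
                            and w.label != v.label]
                w = same_seg[int(rng.integers(len(same_seg)))]
                row.update(
                    truth_class="collision",
                    variant=f"collision({v.label},{w.label})",
                    insert_seq2=design.variant_seq(w),
                    minor_frac=rng.uniform(0.2, 0.5),
                )
            rows.append(row)

    # wild-type-protein (synonymous) control barcodes
    n_syn = rng.poisson(config.synonymous_rate * len(rows))
    for _ in range(int(n_syn)):
        pos = int(rng.integers(1, design.L + 1))
        seg = design.segment_of(pos)
        wt_codon = design.codon(pos)
        from .design import CODONS_BY_AA
        aa = design.protein[pos - 1]
        alts = [c for c in CODONS_BY_AA[aa] if c != wt_codon]
        if not alts:
            continue
        codon = alts[int(rng.integers(len(alts)))]
        s, _ = design.segment_nt_range(seg)
        off = 3 * (pos - 1) - s
        seg_seq = design.segment_seq(seg)
        rows.append({
            "truth_class": "synonymous",
            "variant": f"syn({aa}{pos})",
            "position": pos,
            "wt_aa": aa,
            "mut_aa": aa,
            "segment": seg,
            "true_activity": 1.0,
            "insert_seq": seg_seq[:off] + codon + seg_seq[off + 3 :],
            "insert_seq2": "",
            "minor_frac": 0.0,
        })

    lib = pd.DataFrame(rows)
    lib.insert(0, "barcode", _random_barcodes(len(lib), rng))
    return lib


def simulate_mapping_reads(
    design: ReceptorDesign, config: SimulationConfig
) -> tuple[pd.DataFrame, list[str]]:
    """Ground-truth library plus pre-merged mapping reads.

    Each read is the 15-nt barcode followed by the insert sequence, with
    per-base substitution errors at ``seq_error_rate``. Chimera/collision
    barcodes emit a mixture of two inserts at the recorded minor fraction.
    """
    library = simulate_library(design, config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    reads: list[str] = []
    for row in library.itertuples(index=False):
        n_reads = int(rng.poisson(config.reads_per_barcode))
        for _ in range(n_reads):
            if row.insert_seq2 and rng.random() < row.minor_frac:
                insert = row.insert_seq2
            else:
                insert = row.insert_seq
            reads.append(row.barcode + _add_read_errors(insert, config.seq_error_rate, rng))
    return library, reads


def _nb_draw(mean: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """NB(m, alpha) with var = m + alpha m^2, as a gamma-Poisson mixture."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_counts(library: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Per-condition, per-replicate barcode count table (long format).

    Cell abundance lambda_b is lognormal; each column's expected counts are
    ``depth * w_b / sum(w)`` where w_b = lambda_b for forskolin (maximal,
    receptor-independent induction) and lambda_b * f(a_b, dose) for agonist
    conditions; counts are negative binomial with the configured dispersion,
    independent across replicates.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = len(library)
    lam = rng.lognormal(0.0, config.abundance_sigma, n)
    a = library["true_activity"].to_numpy(dtype=float)

    frames = []
    for cond in CONDITIONS:
        if cond == "forskolin":
            w = lam
        else:
            w = lam * hill_response(a, config.doses[cond], config)
        mean = config.depth * w / w.sum()
        for rep in range(1, config.n_replicates + 1):
            counts = _nb_draw(mean, config.nb_dispersion, rng)
            frames.append(pd.DataFrame({
                "barcode": library["barcode"].to_numpy(),
                "condition": cond,
                "replicate": rep,
                "count": counts,
            }))
    return pd.concat(frames, ignore_index=True)


def expected_relative_activity(library: pd.DataFrame, config: SimulationConfig,
                               condition: str = "EC100") -> pd.Series:
    """Expected measured activity per barcode: f(a, dose) / f(floor, dose)."""
    num = hill_response(library["true_activity"].to_numpy(), config.doses[condition], config)
    den = float(hill_response(config.frameshift_floor, config.doses[condition], config))
    return pd.Series(num / den, index=library["barcode"], name=condition)
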