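"""Binary mutation presence/absence matrices from a multiple sequence alignment.

Each column of the (already aligned) MSA that differs from a chosen reference
sequence yields one binary feature per observed alternate state — a
substitution base or a deletion — coded 1 when the sequence carries it.
Quality filters follow common practice for viral consensus genomes:

* ambiguous bases (N and other non-ACGT codes) are missing data,
* deletion runs longer than ``long_deletion_nt`` are recoded as missing
  (they are usually alignment/assembly artifacts, not real variation),
* features observed in only one sequence are dropped,
* features within the first/last ``flank_trim`` reference positions are
  dropped (poorly covered ends).

Positions are 1-based on the reference after removing reference-gap columns.
The module also provides the attribution-driven QC (missingness correlation)
and the percentile-threshold marker identification used downstream.
"""
from __future__ import annotations

import dataclasses
import itertools
import math
import warnings
from typing import Sequence

import numpy as np
from scipy.stats import spearmanr

from ._errors import FormatError, ParameterError
from .attribution import AttributionMatrix, aggregate_by_group
from .io import DataMatrix

_BASES = {"A", "C", "G", "T"}
_DEL = "del"


@dataclasses.dataclass(frozen=True)
class Variant:
    """One binary feature: an alternate state at a reference position."""

    position: int  # 1-based reference coordinate
    ref: str
    alt: str  # a base or the deletion token "del"

    @property
    def name(self) -> str:
        return f"{self.ref}{self.position}{self.alt}"


@dataclasses.dataclass
class MutationMatrix:
    values: np.ndarray  # (n, m) 0/1
    mask: np.ndarray  # (n, m) True where the call is missing (value forced 0)
    features: list[Variant]
    sample_ids: list[str]
    reference_id: str
    reference_seq: str = ""  # ungapped reference
    imputed: bool = False
    pre_imputation_missingness: np.ndarray | None = None

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.features]

    def missingness(self) -> np.ndarray:
        """Per-feature fraction of masked calls."""
        return self.mask.mean(axis=0)

    def to_data_matrix(self) -> DataMatrix:
        if self.mask.any():
            raise ParameterError("matrix still has missing calls; impute first")
        return DataMatrix(
            self.values.astype(float), self.feature_names, list(self.sample_ids)
        )


def read_alignment(path) -> list[tuple[str, str]]:
    """Read an aligned FASTA into (id, sequence) pairs."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def _states_for(seq: str, ref_cols: np.ndarray, long_deletion_nt: int) -> list[str | None]:
    """Per reference position: base, "del", or None (missing)."""
    states: list[str | None] = []
    for col in ref_cols:
        ch = seq[col].upper()
        if ch == "-":
            states.append(_DEL)
        elif ch in _BASES:
            states.append(ch)
        else:  # N and other ambiguity codes
            states.append(None)
    # recode long deletion runs as missing across their span
    i = 0
    L = len(states)
    while i < L:
        if states[i] == _DEL:
            j = i
            while j < L and states[j] == _DEL:
                j += 1
            if j - i > long_deletion_nt:
                for k in range(i, j):
                    states[k] = None
            i = j
        else:
            i += 1
    return states


def encode_mutations(
    msa: Sequence[tuple[str, str]] | dict,
    reference_id: str,
    flank_trim: int = 100,
    long_deletion_nt: int = 12,
) -> MutationMatrix:
    """Encode an aligned set of sequences against a reference (see module docs)."""
    if isinstance(msa, dict):
        msa = list(msa.items())
    ids = [sid for sid, _ in msa]
    seqs = {sid: s for sid, s in msa}
    if reference_id not in seqs:
        raise FormatError(f"reference id {reference_id!r} not present in the alignment")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise FormatError(f"ragged alignment: sequence lengths {sorted(lengths)}")
    ref_aln = seqs[reference_id].upper()
    ref_cols = np.array([c for c, ch in enumerate(ref_aln) if ch != "-"], dtype=int)
    ref_seq = "".join(ref_aln[c] for c in ref_cols)
    L = len(ref_cols)
    sample_ids = [sid for sid in ids if sid != reference_id]
    state_rows = [_states_for(seqs[sid], ref_cols, long_deletion_nt) for sid in sample_ids]
    features: list[Variant] = []
    cols_vals: list[np.ndarray] = []
    cols_mask: list[np.ndarray] = []
    for p in range(L):
        pos = p + 1
        if pos <= flank_trim or pos > L - flank_trim:
            continue
        ref_base = ref_seq[p]
        col = [row[p] for row in state_rows]
        missing = np.array([st is None for st in col])
        alts = sorted({st for st in col if st is not None and st != ref_base})
        for alt in alts:
            carriers = np.array([st == alt for st in col])
            if carriers.sum() < 2:  # singleton features dropped
                continue
            features.append(Variant(position=pos, ref=ref_base, alt=alt))
            cols_vals.append(carriers.astype(np.int8))
            cols_mask.append(missing)
    if features:
        values = np.column_stack(cols_vals)
        mask = np.column_stack(cols_mask)
    else:
        values = np.zeros((len(sample_ids), 0), dtype=np.int8)
        mask = np.zeros((len(sample_ids), 0), dtype=bool)
    values[mask] = 0
    return MutationMatrix(
        values=values,
        mask=mask,
        features=features,
        sample_ids=sample_ids,
        reference_id=reference_id,
        reference_seq=ref_seq,
    )


def decode(M: MutationMatrix) -> list[tuple[str, str]]:
    """Reconstruct aligned sequences (reference coordinates) from the matrix.

    Positions with no recorded feature are rendered as reference; masked
    calls become N over their positions.  Useful for round-trip checks.
    """
    out = []
    for i, sid in enumerate(M.sample_ids):
        chars = list(M.reference_seq)
        for j, feat in enumerate(M.features):
            p = feat.position - 1
            if M.mask[i, j]:
                chars[p] = "N"
            elif M.values[i, j]:
                chars[p] = "-" if feat.alt == _DEL else feat.alt
        out.append((sid, "".join(chars)))
    return out


def impute_missing(M: MutationMatrix, strategy: str = "reference") -> MutationMatrix:
    """Replace missing calls by the reference state (0); keep the frequencies."""
    if strategy != "reference":
        raise ParameterError(f"unknown imputation strategy {strategy!r}")
    out = MutationMatrix(
        values=M.values.copy(),
        mask=np.zeros_like(M.mask),
        features=list(M.features),
        sample_ids=list(M.sample_ids),
        reference_id=M.reference_id,
        reference_seq=M.reference_seq,
        imputed=True,
        pre_imputation_missingness=M.missingness(),
    )
    return out


def cluster_missingness(M: MutationMatrix, labels: Sequence) -> dict:
    """Per-cluster per-feature missingness frequency."""
    labels = np.asarray(labels)
    return {
        g: M.mask[labels == g].mean(axis=0) for g in sorted(set(labels.tolist()))
    }


def _spearman_perm_pvalue(attr: np.ndarray, miss: np.ndarray, n_permutations: int, seed: int):
    if np.ptp(attr) == 0 or np.ptp(miss) == 0:
        return None, None  # zero variance: correlation undefined
    rho = spearmanr(attr, miss).statistic
    if not np.isfinite(rho):
        return None, None
    m = attr.size
    if math.factorial(m) <= n_permutations:  # exact enumeration for tiny m
        perms = itertools.permutations(range(m))
        stats = [spearmanr(attr, miss[list(p)]).statistic for p in perms]
        stats = np.array(stats)
        p = float(np.mean(stats >= rho - 1e-12))
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            if spearmanr(attr, rng.permutation(miss)).statistic >= rho - 1e-12:
                count += 1
        p = (1 + count) / (n_permutations + 1)
    return float(rho), p


def qc_missingness_correlation(
    A: AttributionMatrix | np.ndarray,
    cluster_labels: Sequence,
    missingness: dict | np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
    min_cluster_size: int = 3,
) -> dict:
    """Per cluster: Spearman correlation of mean |attribution| vs missingness.

    A positive, significant correlation flags clusters whose placement is
    driven by shared missing-data patterns rather than real variation —
    the signal to impute.  One-sided permutation p-values (exact for <= 6
    features, else ``n_permutations`` seeded draws).
    """
    labels = np.asarray(cluster_labels)
    groups, agg = aggregate_by_group(A, labels)
    report = {}
    for gi, g in enumerate(groups):
        size = int((labels == g).sum())
        if size < min_cluster_size:
            warnings.warn(f"cluster {g!r} has fewer than {min_cluster_size} members; skipped")
            continue
        miss = missingness[g] if isinstance(missingness, dict) else np.asarray(missingness)
        rho, p = _spearman_perm_pvalue(agg[gi], np.asarray(miss, float), n_permutations, seed + gi)
        report[g] = {
            "spearman": rho,
            "p_value": p,
            "n_members": size,
            "defined": rho is not None,
        }
    return report


def identify_markers(
    group_attr: np.ndarray,
    freqs: np.ndarray,
    percentile: float = 90.0,
    group_ids: Sequence | None = None,
    feature_names: Sequence[str] | None = None,
) -> dict:
    """Percentile-threshold marker calls per group.

    A feature is flagged ``by_attribution`` (resp. ``by_frequency``) when its
    group-level attribution (resp. frequency) reaches that group's
    ``percentile`` threshold; the quadrants (both / attribution_only /
    frequency_only / neither) partition each group's features.
    """
    group_attr = np.atleast_2d(np.asarray(group_attr, float))
    freqs = np.atleast_2d(np.asarray(freqs, float))
    if group_attr.shape != freqs.shape:
        raise ParameterError("attribution and frequency matrices must share a shape")
    if not (0.0 <= percentile <= 100.0):
        raise ParameterError("percentile must lie in [0, 100]")
    G, m = group_attr.shape
    ids = list(group_ids) if group_ids is not None else list(range(G))
    names = list(feature_names) if feature_names is not None else list(range(m))
    out = {}
    for gi, g in enumerate(ids):
        ta = np.percentile(group_attr[gi], percentile)
        tf = np.percentile(freqs[gi], percentile)
        by_a = {names[j] for j in range(m) if group_attr[gi, j] >= ta}
        by_f = {names[j] for j in range(m) if freqs[gi, j] >= tf}
        allf = set(names)
        out[g] = {
            "by_attribution": by_a,
            "by_frequency": by_f,
            "both": by_a & by_f,
            "attribution_only": by_a - by_f,
            "frequency_only": by_f - by_a,
            "neither": allf - (by_a | by_f),
            "thresholds": {"attribution": float(ta), "frequency": float(tf)},
        }
    return out
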