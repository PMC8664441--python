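"""Readers and writers for the external file formats of the pipeline.

Internal state order is alphabetical ``A, C, G, T, N, DEL``.  The sync
dialect produced by PoPoolation2 ``mpileup2sync`` stores per-sample counts
as colon-separated fields in the order ``A:T:C:G:N:del``; parsing remaps
these into the internal order and writing maps them back, so round trips
are byte-identical.  Sync positions are 1-based inclusive; internal matrix
columns are 0-based.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

STATES: Tuple[str, ...] = ("A", "C", "G", "T", "N", "DEL")
STATE_INDEX: Dict[str, int] = {s: i for i, s in enumerate(STATES)}
#: Haplotype states that can be called (N carries no ancestry information).
CALLABLE_STATES: Tuple[str, ...] = ("A", "C", "G", "T", "DEL")
NOCALL: int = -1

# PoPoolation2 sync column order A:T:C:G:N:del -> internal row indices
_SYNC_TO_INTERNAL = np.array([0, 3, 1, 2, 4, 5])
_INTERNAL_TO_SYNC = np.argsort(_SYNC_TO_INTERNAL)

LEPMAP_GENOTYPES: Tuple[str, ...] = (
    "AA", "AC", "AG", "AT", "CC", "CG", "CT", "GG", "GT", "TT",
)
# diplotypes are recoded BbHOM -> AA, HET -> AC, BvHOM -> CC
_DIPLO_TO_SLOT = {"BbHOM": 0, "HET": 1, "BvHOM": 4}

DIPLOTYPE_STATES: Tuple[str, ...] = ("BbHOM", "HET", "BvHOM")


class FormatError(ValueError):
    """A file violated its declared dialect."""


class ValidationError(ValueError):
    """Structurally parseable input failed a semantic constraint."""


@dataclass
class LocusCounts:
    """Read counts for one sample at one locus.

    ``counts`` is a 6 x n matrix of non-negative integers: rows are the
    sequence states A, C, G, T, N, DEL and columns the reference positions
    (insertions relative to the reference are not representable).  Column
    sums are the per-position mapped depth.
    """

    locus_id: str
    sample_id: str
    counts: np.ndarray  # (6, n) int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != 6:
            raise ValidationError(
                f"counts for {self.locus_id}/{self.sample_id} must be 6 x n, "
                f"got shape {self.counts.shape}"
            )
        if (self.counts < 0).any():
            raise ValidationError("negative read counts")

    @property
    def n(self) -> int:
        return self.counts.shape[1]

    @property
    def depth(self) -> np.ndarray:
        """Per-position mapped depth (column sums)."""
        return self.counts.sum(axis=0)


class SyncData:
    """All samples' count matrices from one sync file.

    Behaves as a mapping keyed by ``(locus_id, sample_id)``; also keeps the
    locus order, per-locus reference-base strings and the sample order so
    that :func:`write_sync` can reproduce the input byte for byte.
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        counts: Mapping[str, np.ndarray],
        ref_bases: Optional[Mapping[str, str]] = None,
    ) -> None:
        self.sample_ids: List[str] = list(sample_ids)
        # locus -> (S, 6, n)
        self._arr: Dict[str, np.ndarray] = {}
        for locus, arr in counts.items():
            arr = np.asarray(arr, dtype=np.int64)
            if arr.ndim != 3 or arr.shape[0] != len(self.sample_ids) or arr.shape[1] != 6:
                raise ValidationError(f"locus {locus}: expected (S, 6, n) array")
            self._arr[locus] = arr
        self.ref_bases: Dict[str, str] = dict(ref_bases or {})
        for locus, arr in self._arr.items():
            self.ref_bases.setdefault(locus, "N" * arr.shape[2])

    @property
    def loci(self) -> List[str]:
        return list(self._arr)

    def locus_array(self, locus_id: str) -> np.ndarray:
        """(S, 6, n) count array for a locus, samples in file order."""
        return self._arr[locus_id]

    def __getitem__(self, key: Tuple[str, str]) -> LocusCounts:
        locus_id, sample_id = key
        s = self.sample_ids.index(sample_id)
        return LocusCounts(locus_id, sample_id, self._arr[locus_id][s])

    def __contains__(self, key: Tuple[str, str]) -> bool:
        locus_id, sample_id = key
        return locus_id in self._arr and sample_id in self.sample_ids

    def __iter__(self):
        for locus in self._arr:
            for sid in self.sample_ids:
                yield locus, sid

    def __len__(self) -> int:
        return len(self._arr) * len(self.sample_ids)


def parse_sync(path, sample_ids: Optional[Sequence[str]] = None) -> SyncData:
    """Parse a PoPoolation2-style sync file.

    Each line is ``locus_id  pos  ref_base  c1  c2  ...`` with one
    colon-separated ``A:T:C:G:N:del`` count field per sample.  Positions are
    1-based; gaps in the position sequence are zero-filled.  If
    ``sample_ids`` is omitted, samples are named ``s1 .. sK``.
    """
    per_locus: Dict[str, Dict[int, np.ndarray]] = {}
    refs: Dict[str, Dict[int, str]] = {}
    n_samples: Optional[int] = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected >= 4 tab-separated fields")
            locus_id, pos_s, ref = fields[0], fields[1], fields[2]
            try:
                pos = int(pos_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: bad position {pos_s!r}") from None
            if pos < 1:
                raise FormatError(f"{path}:{lineno}: position must be >= 1")
            cols = fields[3:]
            if n_samples is None:
                n_samples = len(cols)
            elif len(cols) != n_samples:
                raise FormatError(
                    f"{path}:{lineno}: {len(cols)} sample fields, expected {n_samples}"
                )
            row = np.zeros((n_samples, 6), dtype=np.int64)
            for s, cfield in enumerate(cols):
                parts = cfield.split(":")
                if len(parts) != 6:
                    raise FormatError(
                        f"{path}:{lineno}: malformed count field {cfield!r}"
                    )
                try:
                    vals = [int(p) for p in parts]
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: malformed count field {cfield!r}"
                    ) from None
                if any(v < 0 for v in vals):
                    raise FormatError(f"{path}:{lineno}: negative count in {cfield!r}")
                row[s, _SYNC_TO_INTERNAL] = vals
            sites = per_locus.setdefault(locus_id, {})
            if pos in sites:
                raise FormatError(f"{path}:{lineno}: duplicate position {pos} for {locus_id}")
            sites[pos] = row
            refs.setdefault(locus_id, {})[pos] = ref

    if n_samples is None:
        raise FormatError(f"{path}: empty sync file")
    if sample_ids is None:
        sample_ids = [f"s{i + 1}" for i in range(n_samples)]
    elif len(sample_ids) != n_samples:
        raise ValidationError(
            f"{len(sample_ids)} sample ids given but file has {n_samples} sample columns"
        )

    counts: Dict[str, np.ndarray] = {}
    ref_bases: Dict[str, str] = {}
    for locus_id, sites in per_locus.items():
        n = max(sites)
        arr = np.zeros((n_samples, 6, n), dtype=np.int64)
        ref = ["N"] * n
        for pos, row in sites.items():
            arr[:, :, pos - 1] = row
            ref[pos - 1] = refs[locus_id][pos]
        counts[locus_id] = arr
        ref_bases[locus_id] = "".join(ref)
    return SyncData(sample_ids, counts, ref_bases)


def write_sync(data: SyncData, path) -> None:
    """Write a :class:`SyncData` back to the sync dialect (inverse of parse)."""
    with open(path, "w") as fh:
        for locus_id in data.loci:
            arr = data.locus_array(locus_id)
            ref = data.ref_bases[locus_id]
            for i in range(arr.shape[2]):
                cols = [
                    ":".join(str(v) for v in arr[s, _SYNC_TO_INTERNAL, i])
                    for s in range(arr.shape[0])
                ]
                fh.write(f"{locus_id}\t{i + 1}\t{ref[i]}\t" + "\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# pedigree

GENERATIONS = ("F0", "F1", "F2")
ROLES = ("grandsire_Bv", "granddam_Bb", "F1_father", "F1_mother", "offspring")
SEXES = ("male", "female", "uncertain", "unknown")


@dataclass
class PedigreeTable:
    """The three-generation cross: one F0 pair, one F1 father, F1 mothers,
    and F2 offspring with family and (for F2) sex labels."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        required = {"sample_id", "generation", "role", "family", "sex"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"pedigree missing columns: {sorted(missing)}")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        bad = set(df["role"]) - set(ROLES)
        if bad:
            raise ValidationError(f"unknown roles: {sorted(bad)}")
        for role in ("grandsire_Bv", "granddam_Bb", "F1_father"):
            k = int((df["role"] == role).sum())
            if k != 1:
                raise ValidationError(f"expected exactly one {role}, found {k}")
        f2 = df[df["generation"] == "F2"]
        if f2["family"].isna().any():
            raise ValidationError("every F2 offspring needs a family label")
        bad_sex = set(df["sex"].dropna()) - set(SEXES)
        if bad_sex:
            raise ValidationError(f"unknown sex labels: {sorted(bad_sex)}")

    def _one(self, role: str) -> str:
        return str(self.table.loc[self.table["role"] == role, "sample_id"].iloc[0])

    @property
    def grandsire(self) -> str:
        return self._one("grandsire_Bv")

    @property
    def granddam(self) -> str:
        return self._one("granddam_Bb")

    @property
    def f1_father(self) -> str:
        return self._one("F1_father")

    @property
    def f1_mothers(self) -> List[str]:
        m = self.table.loc[self.table["role"] == "F1_mother", "sample_id"]
        return [str(x) for x in m]

    @property
    def offspring(self) -> List[str]:
        m = self.table.loc[self.table["role"] == "offspring", "sample_id"]
        return [str(x) for x in m]

    @property
    def sample_ids(self) -> List[str]:
        return [str(x) for x in self.table["sample_id"]]

    def family_of(self, sample_id: str) -> object:
        return self.table.set_index("sample_id").loc[sample_id, "family"]

    @property
    def families(self) -> List[object]:
        f2 = self.table[self.table["role"] == "offspring"]
        return sorted(f2["family"].unique().tolist())

    def offspring_of_family(self, family) -> List[str]:
        f2 = self.table[(self.table["role"] == "offspring") & (self.table["family"] == family)]
        return [str(x) for x in f2["sample_id"]]

    def sex_of(self, sample_id: str) -> str:
        return str(self.table.set_index("sample_id").loc[sample_id, "sex"])

    @property
    def sexes(self) -> Dict[str, str]:
        """sample -> sex for F2 offspring (male/female/uncertain/unknown)."""
        f2 = self.table[self.table["role"] == "offspring"]
        return {str(r.sample_id): str(r.sex) for r in f2.itertuples()}


def parse_pedigree(path) -> PedigreeTable:
    """Parse the pedigree TSV (columns sample_id/generation/role/family/sex).

    A missing sex column defaults every F2 to ``unknown`` (with a warning):
    the diplotyping itself never needs sex, only the sex scan does.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "family": "Int64"})
    if "sex" not in df.columns:
        log.warning("pedigree %s has no sex column; all F2 sexes set to 'unknown'", path)
        df["sex"] = "unknown"
    df["sex"] = df["sex"].fillna("unknown")
    ped = PedigreeTable(df)
    for fam in ped.families:
        log.info("family %s: %d F2 offspring", fam, len(ped.offspring_of_family(fam)))
    return ped


def write_pedigree(ped: PedigreeTable, path) -> None:
    ped.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# linkage map


@dataclass
class MapTable:
    """Loci placed on linkage groups at cM positions.

    Loci sharing an (LG, cM) coordinate form a *bin*.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        required = {"locus_id", "linkage_group", "position_cM"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"map missing columns: {sorted(missing)}")
        if df["locus_id"].duplicated().any():
            dups = df.loc[df["locus_id"].duplicated(), "locus_id"].tolist()
            raise ValidationError(f"duplicate locus ids in map: {dups}")
        if (df["position_cM"] < 0).any():
            raise ValidationError("negative cM position in map")
        self.table = df.sort_values(
            ["linkage_group", "position_cM", "locus_id"], kind="stable"
        ).reset_index(drop=True)

    @property
    def linkage_groups(self) -> List[int]:
        return sorted(int(g) for g in self.table["linkage_group"].unique())

    def loci_of(self, lg: int) -> pd.DataFrame:
        return self.table[self.table["linkage_group"] == lg]

    def bins(self) -> Iterable[Tuple[Tuple[int, float], List[str]]]:
        """Yield ((LG, cM), member locus ids), sorted."""
        for (lg, cm), grp in self.table.groupby(
            ["linkage_group", "position_cM"], sort=True
        ):
            yield (int(lg), float(cm)), [str(x) for x in grp["locus_id"]]

    def position_of(self, locus_id: str) -> Tuple[int, float]:
        row = self.table.set_index("locus_id").loc[locus_id]
        return int(row["linkage_group"]), float(row["position_cM"])


def parse_map(path) -> MapTable:
    """Parse a linkage-map TSV with columns locus_id/linkage_group/position_cM."""
    df = pd.read_csv(path, sep="\t", dtype={"locus_id": str})
    return MapTable(df)


def write_map(mt: MapTable, path) -> None:
    mt.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Lep-MAP3 output


def _fmt(x: float) -> str:
    return format(x, ".6g")


def write_lepmap_posterior(
    calls: Mapping[str, Mapping[str, "object"]],
    pedigree: PedigreeTable,
    path,
    pedigree_path=None,
) -> None:
    """Write diplotype calls as a Lep-MAP3 posterior file.

    Diplotypes are recoded BbHOM -> AA, HET -> AC, BvHOM -> CC.  Each line is
    ``locus_id  pos`` followed by one field per individual with ten
    space-separated relative likelihoods in the canonical genotype order
    (AA AC AG AT CC CG CT GG GT TT).  The best diplotype is 1 and the other
    two diplotypes carry ``exp(lnL - lnL_best)``; genotypes outside the
    recoding are 0.  MISSING calls get an uninformative all-equal vector.
    """
    samples = pedigree.sample_ids
    with open(path, "w") as fh:
        fh.write("CHR\tPOS\t" + "\t".join(samples) + "\n")
        for idx, (locus_id, locus_calls) in enumerate(calls.items(), start=1):
            missing = [s for s in samples if s not in locus_calls]
            if missing:
                raise ValidationError(
                    f"locus {locus_id}: no call for pedigree member(s) {missing}"
                )
            fields = []
            for s in samples:
                call = locus_calls[s]
                vec = [0.0] * 10
                if getattr(call, "state", "MISSING") == "MISSING" or call.lnL is None:
                    vec = [1.0] * 10
                else:
                    lnl = np.asarray(call.lnL, dtype=float)
                    rel = np.exp(lnl - lnl.max())
                    for diplo, slot in _DIPLO_TO_SLOT.items():
                        vec[slot] = float(rel[DIPLOTYPE_STATES.index(diplo)])
                fields.append(" ".join(_fmt(v) for v in vec))
            fh.write(f"{locus_id}\t{idx}\t" + "\t".join(fields) + "\n")
    if pedigree_path is not None:
        write_lepmap_pedigree(pedigree, pedigree_path)


def write_lepmap_pedigree(pedigree: PedigreeTable, path) -> None:
    """Write the companion 6-row Lep-MAP3 pedigree (family, id, father,
    mother, sex code, phenotype).  Shared F0/F1 individuals are listed once
    under the first F2 family; Lep-MAP3's half-sib handling joins families
    through the common father."""
    sire, dam, father = pedigree.grandsire, pedigree.granddam, pedigree.f1_father
    mothers = pedigree.f1_mothers
    tbl = pedigree.table.set_index("sample_id")
    fam_of_mother: Dict[str, object] = {}
    fams = pedigree.families
    for i, m in enumerate(mothers):
        fam = tbl.loc[m, "family"]
        fam_of_mother[m] = fam if not pd.isna(fam) else (fams[i] if i < len(fams) else i + 1)

    rows: List[Tuple[object, str, str, str, int, int]] = []
    first_fam = fams[0] if fams else 1
    rows.append((first_fam, sire, "0", "0", 1, 0))
    rows.append((first_fam, dam, "0", "0", 2, 0))
    rows.append((first_fam, father, sire, dam, 1, 0))
    for m in mothers:
        rows.append((fam_of_mother[m], m, sire, dam, 2, 0))
    sex_code = {"male": 1, "female": 2}
    for o in pedigree.offspring:
        fam = tbl.loc[o, "family"]
        mother = next((m for m in mothers if fam_of_mother[m] == fam), mothers[0])
        sx = sex_code.get(str(tbl.loc[o, "sex"]), 0)
        rows.append((fam, o, father, mother, sx, 0))

    with open(path, "w") as fh:
        for r, name in enumerate(["family", "id", "father", "mother", "sex", "pheno"]):
            fh.write(
                "CHR\tPOS\t" + "\t".join(str(row[r]) for row in rows) + "\n"
            )


# ---------------------------------------------------------------------------
# diplotype matrix


def write_diplotype_matrix(
    calls: Mapping[str, Mapping[str, "object"]], path
) -> None:
    """Write a loci x samples TSV of diplotype states plus support columns.

    Each sample contributes two columns: the called state (BbHOM/HET/BvHOM
    or NA) and the ln-likelihood support of the call (NA when missing).
    """
    sample_ids: List[str] = []
    for locus_calls in calls.values():
        for s in locus_calls:
            if s not in sample_ids:
                sample_ids.append(s)
    with open(path, "w") as fh:
        header = ["locus_id"]
        for s in sample_ids:
            header += [s, f"{s}.support"]
        fh.write("\t".join(header) + "\n")
        for locus_id, locus_calls in calls.items():
            row = [locus_id]
            for s in sample_ids:
                call = locus_calls.get(s)
                if call is None or call.state == "MISSING":
                    row += ["NA", "NA"]
                else:
                    row += [call.state, _fmt(float(call.support))]
            fh.write("\t".join(row) + "\n")


def read_diplotype_matrix(path) -> Dict[str, Dict[str, Tuple[str, float]]]:
    """Inverse of :func:`write_diplotype_matrix`.

    Returns ``{locus: {sample: (state, support)}}`` with MISSING for NA
    entries (support ``nan``).
    """
    out: Dict[str, Dict[str, Tuple[str, float]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "locus_id":
            raise FormatError(f"{path}: bad diplotype-matrix header")
        sample_ids = header[1::2]
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise FormatError(f"{path}:{lineno}: wrong number of fields")
            locus = fields[0]
            out[locus] = {}
            for i, s in enumerate(sample_ids):
                state, supp = fields[1 + 2 * i], fields[2 + 2 * i]
                if state == "NA":
                    out[locus][s] = ("MISSING", math.nan)
                else:
                    if state not in DIPLOTYPE_STATES:
                        raise FormatError(f"{path}:{lineno}: bad state {state!r}")
                    out[locus][s] = (state, float(supp))
    return out


# ---------------------------------------------------------------------------
# variant whitelist


@dataclass(frozen=True)
class WhitelistEntry:
    position: int  # 1-based
    state_bv: str
    state_bb: str


def read_variant_whitelist(
    path, locus_lengths: Optional[Mapping[str, int]] = None
) -> Dict[str, List[WhitelistEntry]]:
    """Read manually annotated diagnostic variants for the rescoring path.

    TSV columns ``locus_id / position / state_bv / state_bb``; positions are
    1-based, states in {A,C,G,T,DEL}.  A row whose two taxon states coincide
    is uninformative and rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={"locus_id": str})
    required = {"locus_id", "position", "state_bv", "state_bb"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"whitelist missing columns: {sorted(missing)}")
    out: Dict[str, List[WhitelistEntry]] = {}
    for row in df.itertuples():
        for st in (row.state_bv, row.state_bb):
            if st not in CALLABLE_STATES:
                raise ValidationError(
                    f"whitelist state {st!r} for {row.locus_id} not in {CALLABLE_STATES}"
                )
        if row.state_bv == row.state_bb:
            raise ValidationError(
                f"whitelist position {row.locus_id}:{row.position} is uninformative "
                "(identical taxon states)"
            )
        pos = int(row.position)
        if pos < 1:
            raise ValidationError(f"whitelist position {pos} < 1")
        if locus_lengths is not None:
            n = locus_lengths.get(str(row.locus_id))
            if n is not None and pos > n:
                raise ValidationError(
                    f"whitelist position {row.locus_id}:{pos} beyond locus length {n}"
                )
        out.setdefault(str(row.locus_id), []).append(
            WhitelistEntry(pos, str(row.state_bv), str(row.state_bb))
        )
    return out
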