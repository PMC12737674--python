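"""Seeded generator of labeled contigs and matching hit tables.

The generator emulates the input structure the screening funnel assumes,
with ground truth known by construction:

======  ==========================================================
label   design
======  ==========================================================
H       nuclear host transcript: one standard-code complete ORF
        (>=120 aa, no internal TGA) + high-identity host protein hit
M       mitovirus-like: mito-table-only single ORF carrying the RdRP
        motif + a "...mitovirus..." titled protein hit
R       retroplasmid-like: mito-table-only single ORF (>=300 aa)
        carrying the reverse-transcriptase motif, in-frame TGA codons
        truncating the standard-code reading below 100 aa + a
        divergent non-host hit (40-60% identity, no "virus" in title)
G2      group-II-intron-like: mito-table ORF carrying reverse
        transcriptase + maturase + HNH motifs + a divergent hit
P       partitivirus-like trio of segments sharing configurable
        5'/3' termini, virus-titled hits
C       host transcript with a 300-nt host block misassembled at one
        end + a matching terminal nucleotide-level host hit
N       random noncoding sequence, no hits
======  ==========================================================

Every element is rejection-sampled until its class-defining invariants hold
(also after optional point mutation), so a zero-noise dataset is recovered
exactly by the pipeline. All randomness flows from one seed through a single
numpy generator; regeneration from (seed, params) is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coding import classify_coding_system
from .codes import find_orfs, get_code
from .motifs import (
    HNH,
    MATURASE,
    RDRP,
    RVT,
    MotifDefinition,
    classify_element,
    default_motifs,
    load_motif_config,
    motif_presence,
    parse_pattern,
    scan_motifs,
)
from .seq import Contig, write_fasta
from .termini import conserved_termini
from .triage import HitRecord, flag_end_contamination, write_hit_table

CLASSES = ("H", "M", "R", "G2", "P", "C", "N")

HOST = "Botrytis cinerea"
AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA_NO_W = AA20.replace("W", "")  # mito ORF bodies get Trp planted explicitly
BASES = "ACGT"

DEFAULT_P_TERMINI = ("GCGCAAA", "AATCC")


class GenerationError(RuntimeError):
    """Class constraints unreachable within the retry budget."""


@dataclass
class SyntheticDataset:
    contigs: list[Contig]
    labels: dict[str, str]
    protein_hits: list[HitRecord]
    nucleotide_hits: list[HitRecord]
    segment_groups: dict[str, tuple[str, ...]]
    seed: int
    params: dict

    def contig(self, contig_id: str) -> Contig:
        return next(c for c in self.contigs if c.id == contig_id)


# --------------------------------------------------------------------------
# low-level randomness
# --------------------------------------------------------------------------

def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


def _rand_protein(rng: np.random.Generator, n: int, alphabet: str = AA_NO_W) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


def _mutate(rng: np.random.Generator, sequence: str, rate: float) -> str:
    if rate <= 0:
        return sequence
    hit = rng.random(len(sequence)) < rate
    out = list(sequence)
    for p in np.nonzero(hit)[0]:
        choices = [b for b in BASES if b != out[p]]
        out[p] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def mutate(sequence: str, rate: float, seed: int) -> str:
    """Per-site independent substitution to a uniformly chosen different base."""
    if not (0 <= rate <= 1):
        raise ValueError("rate must be in [0, 1]")
    return _mutate(np.random.default_rng(seed), sequence, rate)


def _mutate_exact(rng: np.random.Generator, sequence: str, n_subs: int) -> str:
    """Substitute exactly ``n_subs`` distinct positions (bounded divergence)."""
    out = list(sequence)
    for p in rng.choice(len(sequence), size=n_subs, replace=False):
        choices = [b for b in BASES if b != out[p]]
        out[p] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def _codons_for(table_id: int, aa: str) -> list[str]:
    code = get_code(table_id)
    return sorted(c for c, a in code.codon_map.items() if a == aa)


def _reverse_translate(
    rng: np.random.Generator, protein: str, table_id: int, w_codon: str | None = None
) -> str:
    codons = []
    for aa in protein:
        if aa == "W" and w_codon is not None:
            codons.append(w_codon)
            continue
        options = _codons_for(table_id, aa)
        codons.append(options[rng.integers(0, len(options))])
    return "".join(codons)


def _sample_motif(rng: np.random.Generator, motif: MotifDefinition) -> str:
    out = []
    for kind, payload in parse_pattern(motif.pattern):
        if kind == "res":
            out.append(payload)
        elif kind == "cls":
            out.append(payload[rng.integers(0, len(payload))])
        elif kind == "neg":
            allowed = [a for a in AA_NO_W if a not in payload]
            out.append(allowed[rng.integers(0, len(allowed))])
        else:
            lo, hi = payload
            out.append(_rand_protein(rng, int(rng.integers(lo, hi + 1))))
    return "".join(out)


def _mito_protein(
    rng: np.random.Generator,
    n_aa: int,
    planted: Sequence[MotifDefinition],
) -> str:
    """Random protein with Trp every 40-60 residues (in-frame TGA anchors when
    reverse-translated with TGA=W) and the given motifs spliced in order."""
    chunks: list[str] = []
    total = 0
    while total < n_aa:
        step = int(rng.integers(40, 61))
        chunks.append(_rand_protein(rng, step))
        chunks.append("W")
        total += step + 1
    body = list("".join(chunks)[:n_aa])
    if planted:
        slots = np.sort(rng.choice(np.arange(5, max(6, len(body) - 5)),
                                   size=len(planted), replace=False))
        for pos, motif in zip(reversed(slots), reversed(list(planted))):
            body[pos:pos] = list(_sample_motif(rng, motif))
    return "".join(body)


# --------------------------------------------------------------------------
# hit fabrication
# --------------------------------------------------------------------------

def _hit(
    rng: np.random.Generator,
    query_id: str,
    subject_id: str,
    title: str,
    organism: str,
    identity: float,
    span: tuple[int, int],
    coverage: float | None = None,
) -> HitRecord:
    qstart, qend = span
    length = qend - qstart + 1
    return HitRecord(
        query_id=query_id,
        subject_id=subject_id,
        percent_identity=round(identity, 1),
        alignment_length=length,
        query_start=qstart,
        query_end=qend,
        subject_start=1,
        subject_end=length,
        evalue=float(f"{10.0 ** -rng.uniform(20, 120):.2e}"),
        bitscore=round(float(rng.uniform(80, 400)), 1),
        query_coverage=None if coverage is None else round(coverage, 1),
        subject_title=title,
        subject_organism_label=organism,
    )


# --------------------------------------------------------------------------
# class builders: each returns (contigs, protein_hits, nucleotide_hits, meta)
# --------------------------------------------------------------------------

def _build_host_body(rng: np.random.Generator, cid: str, orf_aa: tuple[int, int]):
    n_aa = int(rng.integers(*orf_aa))
    protein = "M" + _rand_protein(rng, n_aa - 1, AA20)
    cds = _reverse_translate(rng, protein, table_id=1)
    utr5 = _rand_seq(rng, int(rng.integers(25, 70)))
    utr3 = _rand_seq(rng, int(rng.integers(25, 70)))
    seq = utr5 + cds + "TAA" + utr3
    return seq, len(utr5), len(cds)


def _build_H(rng, cid):
    seq, _, _ = _build_host_body(rng, cid, (140, 260))
    contig = Contig(cid, seq, "synthetic host transcript")
    hit = _hit(
        rng, cid, f"XP_{rng.integers(10**6, 10**7)}",
        f"hypothetical protein BCIN_{rng.integers(1, 17):02d}g{rng.integers(1, 9999):05d} [Botrytis cinerea]",
        HOST, identity=float(rng.uniform(94, 99.5)),
        span=(1, len(seq) // 2), coverage=float(rng.uniform(85, 99)),
    )
    return [contig], [hit], [], {}


_R_SOURCES = (
    ("AAF89327.2", "hypothetical protein [Trichoderma harzianum]", "Trichoderma harzianum"),
    ("AAD38504.1", "reverse transcriptase pFOXC-like [Fusarium oxysporum]", "Fusarium oxysporum"),
)


def _build_mito_element(rng, cid, n_aa_range, planted, motifs_by_name):
    n_aa = int(rng.integers(*n_aa_range))
    protein = "M" + _mito_protein(rng, n_aa, [motifs_by_name[p] for p in planted])
    cds = _reverse_translate(rng, protein, table_id=4, w_codon="TGA")
    utr5 = _rand_seq(rng, int(rng.integers(20, 60)))
    utr3 = _rand_seq(rng, int(rng.integers(20, 60)))
    stop = "TAA" if rng.integers(0, 2) == 0 else "TAG"
    return Contig(cid, utr5 + cds + stop + utr3, "synthetic mitochondrial element")


def _build_R(rng, cid, motifs_by_name):
    contig = _build_mito_element(rng, cid, (300, 420), (RVT,), motifs_by_name)
    acc, title, organism = _R_SOURCES[int(rng.integers(0, len(_R_SOURCES)))]
    hit = _hit(
        rng, cid, acc, title, organism,
        identity=float(rng.uniform(40, 60)),
        span=(1, int(contig.length * 0.8)), coverage=float(rng.uniform(60, 95)),
    )
    return [contig], [hit], [], {}


def _build_M(rng, cid, motifs_by_name):
    contig = _build_mito_element(rng, cid, (280, 400), (RDRP,), motifs_by_name)
    k = int(rng.integers(1, 10))
    hit = _hit(
        rng, cid, f"MT{rng.integers(10**5, 10**6)}",
        f"Botrytis cinerea mitovirus {k} isolate SYN_DN{rng.integers(1000, 9999)}",
        f"Botrytis cinerea mitovirus {k}",
        identity=float(rng.uniform(85, 98)),
        span=(1, int(contig.length * 0.9)), coverage=float(rng.uniform(90, 99)),
    )
    return [contig], [hit], [], {}


def _build_G2(rng, cid, motifs_by_name):
    contig = _build_mito_element(rng, cid, (380, 520), (RVT, MATURASE, HNH), motifs_by_name)
    hit = _hit(
        rng, cid, f"YP_{rng.integers(10**7, 10**8)}",
        "hypothetical protein, intron-encoded [Phyllosticta yuccae]",
        "Phyllosticta yuccae",
        identity=float(rng.uniform(72, 85)),
        span=(1, int(contig.length * 0.9)), coverage=float(rng.uniform(90, 99)),
    )
    return [contig], [hit], [], {}


_P_VIRUSES = (
    ("Botryotinia fuckeliana partitivirus 1", ("MN954881", "MN954882", "MN954885")),
    ("Botrytis cinerea partitivirus 3", ("MN954884", "MN954883", "MN954886")),
)


def _build_P(rng, group_id, five: str, three: str):
    """Trio of segments sharing exact 5'/3' termini, divergent elsewhere."""
    virus, accs = _P_VIRUSES[int(rng.integers(0, len(_P_VIRUSES)))]
    # force disagreement right inside the termini boundaries so the strict
    # consensus is exactly the planted motifs
    after5 = list(rng.permutation(list("ACG")))
    before3 = list(rng.permutation(list("ACG")))
    contigs, hits = [], []
    for j in range(3):
        cid = f"{group_id}_s{j + 1}"
        body = _rand_seq(rng, int(rng.integers(500, 1000)))
        seq = five + after5[j] + body + before3[j] + three
        contigs.append(Contig(cid, seq, f"synthetic partitivirus-like segment {j + 1}"))
        hits.append(
            _hit(
                rng, cid, accs[j],
                f"{virus} isolate SYN segment RNA{j + 1}",
                virus,
                identity=float(rng.uniform(89, 99)),
                span=(1, len(seq) - int(rng.integers(5, 40))),
                coverage=float(rng.uniform(92, 99)),
            )
        )
    return contigs, hits, [], {"group": group_id}


def _build_C(rng, cid):
    body, _, _ = _build_host_body(rng, cid, (150, 250))
    block = _rand_seq(rng, 300)
    left = rng.integers(0, 2) == 0
    seq = block + body if left else body + block
    n = len(seq)
    span = (1, 300) if left else (n - 299, n)
    contig = Contig(cid, seq, "synthetic host-end chimera")
    phit = _hit(
        rng, cid, f"XP_{rng.integers(10**6, 10**7)}",
        f"hypothetical protein BCIN_{rng.integers(1, 17):02d}g{rng.integers(1, 9999):05d} [Botrytis cinerea]",
        HOST, identity=float(rng.uniform(94, 99.5)),
        span=(301, n // 2 + 300) if left else (1, n // 2),
        coverage=float(rng.uniform(60, 90)),
    )
    nhit = _hit(
        rng, cid, "CP009805",
        f"Botrytis cinerea B05.10 chromosome {rng.integers(1, 17)}",
        HOST, identity=float(rng.uniform(97, 100)),
        span=span, coverage=round(100.0 * 300 / n, 1),
    )
    return [contig], [phit], [nhit], {"side": "left" if left else "right"}


def _build_N(rng, cid):
    contig = Contig(cid, _rand_seq(rng, int(rng.integers(150, 300))), "synthetic noncoding")
    return [contig], [], [], {}


# --------------------------------------------------------------------------
# class-defining invariant checks (run after optional mutation)
# --------------------------------------------------------------------------

def _element_annotations(contig: Contig, motifs, min_len_aa=100):
    orfs = find_orfs(contig, get_code(4), min_len_aa, completeness_filter=("complete",))
    ann = []
    for orf in orfs:
        ann.extend(scan_motifs(orf.protein, motifs, protein_id=contig.id))
    return ann


def _check_class(label, contigs, meta, motifs, p_termini) -> bool:
    if label == "H":
        return classify_coding_system(contigs[0]).call == "nuclear_coding"
    if label == "N":
        return classify_coding_system(contigs[0]).call == "noncoding"
    if label in ("R", "M", "G2"):
        cc = classify_coding_system(contigs[0])
        if cc.call != "mitochondrial_coding":
            return False
        ann = _element_annotations(contigs[0], motifs)
        present = motif_presence(ann, motifs)
        expected = {
            "R": ({RVT}, "retroplasmid"),
            "M": ({RDRP}, "mitovirus_like"),
            "G2": ({RVT, MATURASE, HNH}, "group_II_intron"),
        }[label]
        if present != expected[0]:
            return False
        if label in ("R", "M") and not cc.single_orf:
            return False
        return classify_element(cc, ann, motifs).element_class == expected[1]
    if label == "P":
        tc = conserved_termini(contigs, max_mismatch=0)
        return (
            tc.five_prime == p_termini[0].replace("T", "U")
            and tc.three_prime == p_termini[1].replace("T", "U")
        )
    if label == "C":
        if classify_coding_system(contigs[0]).call != "nuclear_coding":
            return False
        return True
    raise ValueError(label)


# --------------------------------------------------------------------------
# dataset assembly
# --------------------------------------------------------------------------

def make_dataset(
    seed: int,
    n_per_class: int,
    mutation_rate: float = 0.0,
    motif_config: Sequence[MotifDefinition] | str | Path | None = None,
    p_termini: tuple[str, str] = DEFAULT_P_TERMINI,
    max_retries: int = 120,
) -> SyntheticDataset:
    """Generate a labeled dataset; see the module docstring for class designs.

    ``n_per_class`` counts elements: class P contributes three segment contigs
    per element. Point mutations (``mutation_rate``) are applied after
    construction; an element whose class-defining invariants do not survive is
    regenerated, up to ``max_retries`` attempts.
    """
    if n_per_class < 0:
        raise ValueError("n_per_class must be >= 0")
    if not (0 <= mutation_rate < 0.25):
        raise ValueError("mutation_rate must be in [0, 0.25)")
    if motif_config is None:
        motifs = default_motifs()
    elif isinstance(motif_config, (str, Path)):
        motifs = load_motif_config(motif_config)
    else:
        motifs = list(motif_config)
    motifs_by_name = {m.name: m for m in motifs}
    for needed in (RVT, MATURASE, HNH, RDRP):
        if needed not in motifs_by_name:
            raise GenerationError(f"motif config lacks required role {needed!r}")

    rng = np.random.default_rng(seed)
    contigs: list[Contig] = []
    labels: dict[str, str] = {}
    protein_hits: list[HitRecord] = []
    nucleotide_hits: list[HitRecord] = []
    segment_groups: dict[str, tuple[str, ...]] = {}

    for label in CLASSES:
        for i in range(n_per_class):
            cid = f"{label}{i:03d}"
            for _ in range(max_retries):
                if label == "H":
                    cand = _build_H(rng, cid)
                elif label == "M":
                    cand = _build_M(rng, cid, motifs_by_name)
                elif label == "R":
                    cand = _build_R(rng, cid, motifs_by_name)
                elif label == "G2":
                    cand = _build_G2(rng, cid, motifs_by_name)
                elif label == "P":
                    cand = _build_P(rng, cid, p_termini[0], p_termini[1])
                elif label == "C":
                    cand = _build_C(rng, cid)
                else:
                    cand = _build_N(rng, cid)
                ctgs, phits, nhits, meta = cand
                if mutation_rate > 0:
                    ctgs = [
                        Contig(c.id, _mutate(rng, c.sequence, mutation_rate), c.description)
                        for c in ctgs
                    ]
                if _check_class(label, ctgs, meta, motifs, p_termini):
                    break
            else:
                raise GenerationError(
                    f"could not satisfy class {label!r} invariants for {cid} "
                    f"within {max_retries} attempts"
                )
            contigs.extend(ctgs)
            for c in ctgs:
                labels[c.id] = label
            protein_hits.extend(phits)
            nucleotide_hits.extend(nhits)
            if label == "P":
                segment_groups[cid] = tuple(c.id for c in ctgs)

    return SyntheticDataset(
        contigs=contigs,
        labels=labels,
        protein_hits=protein_hits,
        nucleotide_hits=nucleotide_hits,
        segment_groups=segment_groups,
        seed=seed,
        params={
            "n_per_class": n_per_class,
            "mutation_rate": mutation_rate,
            "p_termini": list(p_termini),
            "motifs": [
                {"name": m.name, "pattern": m.pattern, "min_score": m.min_score}
                for m in motifs
            ],
        },
    )


def make_redundancy_set(
    seed: int,
    n_seeds: int = 15,
    n_copies: int = 109,
    max_divergence: float = 0.03,
    length_range: tuple[int, int] = (800, 1600),
) -> tuple[dict[str, str], dict[str, str]]:
    """Seed sequences plus bounded-divergence, slightly end-trimmed copies.

    Emulates collapsing database hits of an element family back to distinct
    elements: every copy substitutes at most ``max_divergence`` of its sites
    and is strictly shorter than its seed (fragments are redundant with the
    full element). Returns (id -> sequence, id -> true family seed id).
    """
    rng = np.random.default_rng(seed)
    sequences: dict[str, str] = {}
    truth: dict[str, str] = {}
    seed_ids = []
    for i in range(n_seeds):
        sid = f"seed_{i:02d}"
        sequences[sid] = _rand_seq(rng, int(rng.integers(length_range[0], length_range[1] + 1)))
        truth[sid] = sid
        seed_ids.append(sid)
    for j in range(n_copies):
        cid = f"copy_{j:03d}"
        parent = seed_ids[int(rng.integers(0, n_seeds))]
        src = sequences[parent]
        t0 = int(rng.integers(0, 15))
        t1 = int(rng.integers(5, 40))
        frag = src[t0 : len(src) - t1]
        n_subs = int(rng.integers(0, int(max_divergence * len(frag)) + 1))
        sequences[cid] = _mutate_exact(rng, frag, n_subs)
        truth[cid] = parent
    return sequences, truth


# --------------------------------------------------------------------------
# ground-truth scoring and on-disk form
# --------------------------------------------------------------------------

def confusion_matrix(
    labels: Mapping[str, str], predicted: Mapping[str, str]
) -> pd.DataFrame:
    """Rows = true class, columns = predicted class, values = contig counts."""
    ids = sorted(labels)
    df = pd.crosstab(
        pd.Series([labels[i] for i in ids], name="true"),
        pd.Series([predicted.get(i, "missing") for i in ids], name="predicted"),
    )
    return df.reindex(index=sorted(df.index), columns=sorted(df.columns), fill_value=0)


def recovery_rates(
    labels: Mapping[str, str], predicted: Mapping[str, str]
) -> dict[str, float]:
    """Per-class fraction of contigs whose predicted class equals the label."""
    totals: dict[str, int] = {}
    correct: dict[str, int] = {}
    for cid, cls in labels.items():
        totals[cls] = totals.get(cls, 0) + 1
        if predicted.get(cid) == cls:
            correct[cls] = correct.get(cls, 0) + 1
    return {cls: correct.get(cls, 0) / n for cls, n in sorted(totals.items())}


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA + labels TSV + two hit TSVs + segment groups + params JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "contigs": outdir / "contigs.fasta",
        "labels": outdir / "labels.tsv",
        "protein_hits": outdir / "protein_hits.tsv",
        "nucleotide_hits": outdir / "nucleotide_hits.tsv",
        "segment_groups": outdir / "segment_groups.tsv",
        "params": outdir / "params.json",
    }
    write_fasta(dataset.contigs, paths["contigs"])
    with open(paths["labels"], "w") as fh:
        fh.write("contig_id\tlabel\n")
        for c in dataset.contigs:
            fh.write(f"{c.id}\t{dataset.labels[c.id]}\n")
    write_hit_table(dataset.protein_hits, paths["protein_hits"], "outfmt6_ext")
    write_hit_table(dataset.nucleotide_hits, paths["nucleotide_hits"], "outfmt6_ext")
    with open(paths["segment_groups"], "w") as fh:
        fh.write("group_id\tcontig_id\n")
        for gid, members in dataset.segment_groups.items():
            for m in members:
                fh.write(f"{gid}\t{m}\n")
    with open(paths["params"], "w") as fh:
        json.dump({"seed": dataset.seed, "params": dataset.params}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def read_labels(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["contig_id"], df["label"]))
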