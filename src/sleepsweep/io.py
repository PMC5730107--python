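"""Readers and writers for the text formats the pipeline consumes.

Formats: PoPoolation2-style sync (per-sample ``A:T:C:G:N:del`` counts),
long-format count TSV, DAM-style per-minute activity tables with a
lights-schedule sidecar, founder-line genotype matrices (TSV or VCF), and
tidy CSV trait tables.  All writers emit a comment header carrying the
package version, a config hash, and the seeds in play.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .panel import AlleleCountPanel, FounderPanel, SAMPLE_COLUMNS
from .sleep import ActivityTrace, LightsSchedule

log = logging.getLogger("sleepsweep")

_BASES = ["A", "T", "C", "G"]
_SYNC_ORDER = ["A", "T", "C", "G", "N", "del"]


def file_header(config_hash: str = "", seeds: dict | None = None) -> list[str]:
    lines = [f"##sleepsweep_version={__version__}"]
    if config_hash:
        lines.append(f"##config_hash={config_hash}")
    for name, seed in (seeds or {}).items():
        lines.append(f"##seed_{name}={seed}")
    return lines


class SyncParseError(ValueError):
    pass


def write_sync(panel: AlleleCountPanel, path, config_hash: str = "",
               seeds: dict | None = None) -> None:
    """Sync text: chrom, pos, ref, then per-sample colon-separated counts.

    Sample metadata rides in ``##sample`` header lines so a round trip
    preserves population/sex/generation labels.
    """
    sites = panel.sites
    with open(path, "w") as fh:
        for line in file_header(config_hash, seeds):
            fh.write(line + "\n")
        for _, s in panel.samples.iterrows():
            meta = ";".join(f"{k}={s[k]}" for k in SAMPLE_COLUMNS)
            fh.write(f"##sample\t{meta}\n")
        for i in range(panel.n_sites):
            ref, alt = sites.at[i, "ref"], sites.at[i, "alt"]
            fields = [str(sites.at[i, "chrom"]), str(sites.at[i, "pos"]), str(ref)]
            for j in range(panel.n_samples):
                counts = dict.fromkeys(_SYNC_ORDER, 0)
                counts[str(ref)] = int(panel.ref_count[i, j])
                counts[str(alt)] = int(panel.alt_count[i, j])
                fields.append(":".join(str(counts[k]) for k in _SYNC_ORDER))
            fh.write("\t".join(fields) + "\n")


def read_sync(path) -> AlleleCountPanel:
    """Parse sync text into a biallelic count panel.

    The alt allele at each site is the highest-count non-reference base
    across samples; sites with reads on a third allele are flagged
    multi-allelic and excluded (logged with their line numbers).
    Malformed rows raise :class:`SyncParseError` naming the line.
    """
    sample_meta = []
    site_rows = []
    per_site_counts = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("##sample\t"):
                meta = dict(kv.split("=", 1) for kv in line.split("\t", 1)[1].split(";"))
                sample_meta.append(meta)
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise SyncParseError(f"line {lineno}: fewer than 4 columns")
            chrom, pos, ref = fields[0], fields[1], fields[2]
            try:
                pos = int(pos)
            except ValueError as exc:
                raise SyncParseError(f"line {lineno}: bad position {pos!r}") from exc
            counts = []
            for j, cell in enumerate(fields[3:]):
                parts = cell.split(":")
                if len(parts) != 6:
                    raise SyncParseError(
                        f"line {lineno}: sample {j + 1} has {len(parts)} count "
                        "fields, expected 6 (A:T:C:G:N:del)")
                try:
                    counts.append([int(x) for x in parts])
                except ValueError as exc:
                    raise SyncParseError(
                        f"line {lineno}: non-numeric count in sample {j + 1}") from exc
            site_rows.append((lineno, chrom, pos, ref))
            per_site_counts.append(np.array(counts))  # (n_samples, 6)

    n_samples_set = {c.shape[0] for c in per_site_counts}
    if len(n_samples_set) > 1:
        raise SyncParseError("ragged rows: inconsistent sample counts across sites")

    sites, ref_cols, alt_cols = [], [], []
    for (lineno, chrom, pos, ref), counts in zip(site_rows, per_site_counts):
        if ref not in _BASES:
            raise SyncParseError(f"line {lineno}: reference base {ref!r}")
        totals = counts[:, :4].sum(axis=0)
        ref_idx = _BASES.index(ref)
        nonref = [k for k in range(4) if k != ref_idx and totals[k] > 0]
        if len(nonref) > 1:
            log.warning("line %d (%s:%d): multi-allelic site excluded", lineno,
                        chrom, pos)
            continue
        alt_idx = nonref[0] if nonref else (ref_idx + 1) % 4
        sites.append({"chrom": chrom, "pos": pos, "ref": ref,
                      "alt": _BASES[alt_idx]})
        ref_cols.append(counts[:, ref_idx])
        alt_cols.append(counts[:, alt_idx])

    if sample_meta:
        samples = pd.DataFrame(sample_meta)
        samples["generation"] = samples["generation"].astype(int)
        samples["replicate"] = samples["replicate"].astype(int)
    else:
        n = next(iter(n_samples_set)) if n_samples_set else 0
        samples = pd.DataFrame({
            "population": [f"sample_{j}" for j in range(n)],
            "scheme": "", "replicate": 1, "sex": "", "generation": 0,
        })
    return AlleleCountPanel(
        sites=pd.DataFrame(sites),
        samples=samples,
        ref_count=np.vstack(ref_cols) if ref_cols else np.zeros((0, len(samples))),
        alt_count=np.vstack(alt_cols) if alt_cols else np.zeros((0, len(samples))),
    )


def write_long_counts(panel: AlleleCountPanel, path, config_hash: str = "",
                      seeds: dict | None = None) -> None:
    """Long-format TSV: one row per site x sample with ref/alt counts."""
    with open(path, "w") as fh:
        for line in file_header(config_hash, seeds):
            fh.write(line + "\n")
        panel.to_long().to_csv(fh, sep="\t", index=False)


def read_long_counts(path) -> AlleleCountPanel:
    df = pd.read_csv(path, sep="\t", comment="#")
    site_cols = ["chrom", "pos", "ref", "alt"]
    sites = df[site_cols].drop_duplicates().reset_index(drop=True)
    samples = df[SAMPLE_COLUMNS].drop_duplicates().reset_index(drop=True)
    site_key = {tuple(r): i for i, r in enumerate(sites.itertuples(index=False))}
    samp_key = {tuple(r): j for j, r in enumerate(samples.itertuples(index=False))}
    ref = np.zeros((len(sites), len(samples)), dtype=np.int64)
    alt = np.zeros_like(ref)
    si = df[site_cols].apply(tuple, axis=1).map(site_key).to_numpy()
    sj = df[SAMPLE_COLUMNS].apply(tuple, axis=1).map(samp_key).to_numpy()
    ref[si, sj] = df["ref_count"].to_numpy()
    alt[si, sj] = df["alt_count"].to_numpy()
    return AlleleCountPanel(sites=sites, samples=samples, ref_count=ref,
                            alt_count=alt)


# ---------------------------------------------------------------------------
# DAM-style activity tables
# ---------------------------------------------------------------------------

def write_dam(traces: list[ActivityTrace], path, schedule_path=None) -> None:
    """Tab-delimited monitor table: minute index then one column per fly;
    the schedule sidecar records lights-on/lights-off minutes-of-day."""
    if not traces:
        raise ValueError("no traces to write")
    lengths = {t.n_minutes for t in traces}
    if len(lengths) > 1:
        raise ValueError("traces must be equally long")
    mat = np.column_stack([t.counts for t in traces])
    ids = [t.fly_id or f"ch{k + 1}" for k, t in enumerate(traces)]
    with open(path, "w") as fh:
        fh.write("minute\t" + "\t".join(ids) + "\n")
        for m in range(mat.shape[0]):
            fh.write(str(m) + "\t" + "\t".join(map(str, mat[m])) + "\n")
    if schedule_path is not None:
        sched = traces[0].schedule
        with open(schedule_path, "w") as fh:
            fh.write("lights_on_minute\tlights_off_minute\tperiod\n")
            fh.write(f"0\t{sched.day_length}\t{sched.period}\n")


def read_dam(path, schedule_path=None) -> list[ActivityTrace]:
    df = pd.read_csv(path, sep="\t")
    schedule = LightsSchedule()
    if schedule_path is not None:
        s = pd.read_csv(schedule_path, sep="\t").iloc[0]
        schedule = LightsSchedule(day_length=int(s["lights_off_minute"]),
                                  period=int(s["period"]))
    return [
        ActivityTrace(df[col].to_numpy(), schedule, fly_id=col)
        for col in df.columns[1:]
    ]


# ---------------------------------------------------------------------------
# founder genotypes
# ---------------------------------------------------------------------------

def write_founders_tsv(panel: FounderPanel, path) -> None:
    df = panel.sites.copy()
    for k, name in enumerate(panel.line_names):
        df[name] = panel.genotypes[k]
    df.to_csv(path, sep="\t", index=False)


def read_founders_tsv(path) -> FounderPanel:
    df = pd.read_csv(path, sep="\t", comment="#")
    site_cols = ["chrom", "pos", "ref", "alt"]
    line_names = [c for c in df.columns if c not in site_cols]
    return FounderPanel(sites=df[site_cols], genotypes=df[line_names].to_numpy().T,
                        line_names=line_names)


def write_founders_vcf(panel: FounderPanel, path) -> None:
    """Minimal VCF 4.2 with haploid GT calls for the inbred lines."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=sleepsweep {__version__}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in panel.sites["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.line_names) + "\n")
        for i, site in panel.sites.iterrows():
            gts = "\t".join(str(int(g)) for g in panel.genotypes[:, i])
            fh.write(f"{site['chrom']}\t{site['pos']}\t.\t{site['ref']}\t"
                     f"{site['alt']}\t.\tPASS\t.\tGT\t{gts}\n")


def read_founders_vcf(path) -> FounderPanel:
    """Read phased/haploid-coded inbred-line genotypes from a VCF."""
    import pysam

    vf = pysam.VariantFile(str(path))
    line_names = list(vf.header.samples)
    rows, geno = [], []
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            log.warning("%s:%d: not biallelic, skipped", rec.chrom, rec.pos)
            continue
        calls = []
        for name in line_names:
            alleles = rec.samples[name]["GT"]
            first = alleles[0] if alleles else None
            calls.append(0 if first in (None,) else int(first))
        rows.append({"chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref,
                     "alt": rec.alts[0]})
        geno.append(calls)
    return FounderPanel(sites=pd.DataFrame(rows),
                        genotypes=np.array(geno, dtype=np.uint8).T,
                        line_names=line_names)


@dataclass
class TraitTableIO:
    """Tidy CSV round trip for scored sleep traits."""

    @staticmethod
    def write(df: pd.DataFrame, path, config_hash: str = "",
              seeds: dict | None = None) -> None:
        with open(path, "w") as fh:
            for line in file_header(config_hash, seeds):
                fh.write(line + "\n")
            df.to_csv(fh, index=False)

    @staticmethod
    def read(path) -> pd.DataFrame:
        return pd.read_csv(path, comment="#")
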