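"""VCF 4.2 text output for site records.

Hom-ref and no-call records use ALT "." (reference-confirmed sites are a
first-class output here, unlike most variant-only VCFs); the full PL triple
is always written.  Sample provenance rides in INFO (``SID``, ``CENTER``,
``BUILD``) so records from many samples can share one file, with the
genotype column labeled by the pseudonymous system sample ID when the file
is single-sample.
"""

from __future__ import annotations

from typing import Iterable, TextIO

from .genotyper import SiteRecord

_HEADER = """\
##fileformat=VCFv4.2
##source=fedvar
##INFO=<ID=SID,Number=1,Type=String,Description="System sample ID (pseudonym)">
##INFO=<ID=CENTER,Number=1,Type=String,Description="Originating center">
##INFO=<ID=BUILD,Number=1,Type=String,Description="Source genome build">
##FILTER=<ID=REF_N,Description="Reference base unknown">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths (ref,alt)">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred-scaled genotype likelihoods">
"""


def format_record(record: SiteRecord) -> str:
    call = record.call
    info = (f"SID={record.system_sample_id};CENTER={record.center_id};"
            f"BUILD={record.source_build}")
    sample = (f"{call.gt}:{call.ad[0]},{call.ad[1]}:{call.dp}:{call.gq}:"
              f"{call.pl[0]},{call.pl[1]},{call.pl[2]}")
    qual = "." if call.gt == "./." else f"{record.qual:g}"
    return "\t".join([
        record.chrom, str(record.pos), record.dbsnp_id, record.ref,
        record.alt, qual, record.filter, info, "GT:AD:DP:GQ:PL", sample,
    ])


def write_vcf(records: Iterable[SiteRecord], out: TextIO,
              sample_label: str | None = None) -> int:
    """Write records as VCF; returns the number of data lines written."""
    records = list(records)
    if sample_label is None:
        sids = {r.system_sample_id for r in records}
        sample_label = sids.pop() if len(sids) == 1 else "SAMPLE"
    out.write(_HEADER)
    out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
              f"{sample_label}\n")
    count = 0
    for record in sorted(records,
                         key=lambda r: (r.chrom, r.pos, r.system_sample_id)):
        out.write(format_record(record) + "\n")
        count += 1
    return count
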