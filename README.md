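# fedvar

Federated variant querying across sequencing centers, at desk scale.

`fedvar` answers questions like *"which samples, anywhere in the
federation, carry a variant at chr9:2115841?"* without moving raw data
between centers. Each center genotypes its own aligned reads locally and
exports only VCF-like records; the coordinator harmonizes records from
different genome builds onto one target build and aggregates them into
privacy-tiered result views:

- **detailed** rows (full genotype records) only for samples in the user's
  currently *active dataset*;
- **summary statistics** (genotype counts, folded minor-allele frequency,
  quality min/max/mean) for the active set, the control cohorts, and the
  whole population;
- a pseudonymous *system sample ID* as the only backlink to everyone
  else's samples, so relevant carriers can be found and their owners
  contacted without exposing local identifiers.

## Components

| module | role |
| --- | --- |
| `fedvar.registry` | centers, users, PIs, samples, datasets; pseudonymization, dataset activation, access tiers, append-only audit log |
| `fedvar.genotyper` | pileup extraction (TSV fixture dialect or SAM/BAM via pysam) and a built-in diploid genotype-likelihood caller (GT/AD/DP/GQ/PL), including reference-site genotyping (`all_sites` mode); pluggable external-caller hook |
| `fedvar.liftover` | UCSC chain-file reader and position/record harmonization between builds, with a drop report (records are never silently lost) |
| `fedvar.coordinator` | query specs (point / area / gene name), request IDs, per-center task dispatch and tracking, result collection |
| `fedvar.aggregator` | partition summaries, quality filters (incl. PL-margin filter), MAF, Sample-to-SNV clustering, co-carrier analysis, privacy redaction |
| `fedvar.synthetic` | fully deterministic federation fixtures: planted genotypes (Hardy–Weinberg + explicit overrides), pileups with controlled error, manifests, chain files, runnable deployment directories |
| `fedvar.vcfio` | VCF 4.2 writer for site records (hom-ref records carry ALT `.` with full PLs) |

## CLI

A deployment is a directory holding `deployment.yaml`, per-center
manifests/reference tables/pileup data, and optional chain files. Generate
a toy one and query it:

```sh
fedvar demo --out /tmp/demo --seed 1          # build + query in one go

fedvar query point -d /tmp/demo --user res1 \
    --chrom chr9 --pos 2115841 --all-site-pls --min-pl 70
fedvar query area  -d /tmp/demo --user res1 --gene MYGENE
fedvar admin add-sample -d /tmp/demo --center-id C1 --manifest manifest.tsv
fedvar admin create-dataset -d /tmp/demo --dataset-id D1 --name mine \
    --owner res1 --member FV-xxxxxxxx
fedvar user activate-dataset -d /tmp/demo --user res1 --dataset-id D1
```

Query output is the redacted JSON result view; `--out-vcf` additionally
writes the Detail records as VCF.

Sample manifests are TSVs with columns `SampleLocalName`, `PIName`,
`SampleType`, `SampleReferenceVersion`, `DataPath` (the first four are
compulsory). The pileup fixture dialect is a TSV per sample with columns
`chrom`, `pos`, `ref`, `bases`, `quals`.

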