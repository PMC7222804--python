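# Example run manifest: the twelve-genome comparative study.
#
# Sequences are user-supplied (the tool never downloads); fetch them with
#   python scripts/fetch_references.py
# then run
#   mtcpg compare --manifest examples/manifest.yaml
#
# Feature tables come from the GenBank flat files fetched alongside.

outdir: mtcpg-comparative
strands: both

scan:            # island caller
  window: 100
  shift: 1
  min_length: 200
  min_obs_exp: 0.6
  min_pct_cg: 50
seek:            # running-sum detector
  cpg_score: 17
  gap_penalty: 1
  threshold: 17

inputs:
  - {label: Caenorhabditis_elegans, group: invertebrate,
     sequence: data/references/NC_001328.1.fasta,
     features: data/references/NC_001328.1.gb, feature_dialect: genbank}
  - {label: Drosophila_melanogaster, group: invertebrate,
     sequence: data/references/NC_024511.2.fasta,
     features: data/references/NC_024511.2.gb, feature_dialect: genbank}
  - {label: Daphnia_magna, group: invertebrate,
     sequence: data/references/NC_026914.1.fasta,
     features: data/references/NC_026914.1.gb, feature_dialect: genbank}
  - {label: Latimeria_chalumnae, group: vertebrate,
     sequence: data/references/NC_001804.1.fasta,
     features: data/references/NC_001804.1.gb, feature_dialect: genbank}
  - {label: Danio_rerio, group: vertebrate,
     sequence: data/references/NC_002333.2.fasta,
     features: data/references/NC_002333.2.gb, feature_dialect: genbank}
  - {label: Ambystoma_mexicanum, group: vertebrate,
     sequence: data/references/NC_005797.1.fasta,
     features: data/references/NC_005797.1.gb, feature_dialect: genbank}
  - {label: Gallus_gallus, group: vertebrate,
     sequence: data/references/NC_040970.1.fasta,
     features: data/references/NC_040970.1.gb, feature_dialect: genbank}
  - {label: Mus_musculus, group: vertebrate,
     sequence: data/references/NC_005089.1.fasta,
     features: data/references/NC_005089.1.gb, feature_dialect: genbank}
  - {label: Canis_lupus_familiaris, group: vertebrate,
     sequence: data/references/NC_002008.4.fasta,
     features: data/references/NC_002008.4.gb, feature_dialect: genbank}
  - {label: Crocodylus_porosus, group: vertebrate,
     sequence: data/references/NC_008143.1.fasta,
     features: data/references/NC_008143.1.gb, feature_dialect: genbank}
  - {label: Pan_troglodytes_ellioti, group: vertebrate,
     sequence: data/references/KM679417.1.fasta,
     features: data/references/KM679417.1.gb, feature_dialect: genbank}
  - {label: Homo_sapiens, group: vertebrate,
     sequence: data/references/NC_012920.1.fasta,
     features: data/references/NC_012920.1.gb, feature_dialect: genbank}
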