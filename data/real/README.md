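# Deposited cohort placement

This repository distributes no subject-level data.  To run the real-data
reproduction (the `test_real_cohort_reproduces_published_statistics`
acceptance test and any pipeline run with `input_path` pointing here),
download the study's deposited per-subject table from its data repository
and save it as `cohort.tsv` in this directory: a tab-separated file with a
header row and the columns

    id  age  sex  population  5-HTTLPR  rs6265  rs6295  rs6311
    rs7766029  rs7958311  rs8836  rle_count  dep  bsi_dep  bsi_anx

using the genotype level labels of the data dictionary
(`bnbmla.cohort_data.default_dictionary()`), `male`/`female` for sex,
`BUD`/`MAN` for the recruitment site, a non-negative integer recent-life-
event count, a 0/1 lifetime-depression indicator, and weighted BSI scores
in [0, 4].  Missing values are encoded as `NA`; incomplete rows are dropped
during validation (complete-case analysis).
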