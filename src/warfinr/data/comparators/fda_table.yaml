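# FDA warfarin label genotype-based dose-range table, midpoints in mg/day.
# EXTERNAL PROVENANCE: range midpoints from the US warfarin product label
# pharmacogenomics table (ranges 5-7, 3-4 and 0.5-2 mg/day); editable.
name: FDA-table
form: table
scale: daily
provenance: "US warfarin label genotype table, range midpoints"
table:
  "*1/*1": {GG: 6.0, GA: 6.0, AA: 3.5}
  "*1/*2": {GG: 6.0, GA: 3.5, AA: 3.5}
  "*1/*3": {GG: 3.5, GA: 3.5, AA: 1.25}
  "*2/*2": {GG: 3.5, GA: 3.5, AA: 1.25}
  "*2/*3": {GG: 3.5, GA: 1.25, AA: 1.25}
  "*3/*3": {GG: 1.25, GA: 1.25, AA: 1.25}
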