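# cagedit

Analysis toolkit for CAG-to-CAA base editing of the *HTT* CAG repeat — the
glutamine-preserving editing strategy for Huntington's disease (HD).

## Background

HD is caused by an expanded CAG repeat in exon 1 of *HTT*. The repeat is
normally *interrupted*: an uninterrupted CAG tract is followed by a single
CAA–CAG doublet (the **canonical** structure). Because CAA also encodes
glutamine, the protein carries `CAG + 2` glutamines. Rare structural
variants matter clinically: carriers who **lose** the interruption (LOI)
behave like their CAG count is ~3 units larger, while carriers with a
**duplicated** interruption (DI, two CAA–CAG doublets) behave ~1 unit
smaller. The quantity that drives age at onset is therefore the
*uninterrupted* CAG length, not the glutamine count.

A cytosine base editor targeted to the antisense strand converts sense CAG
codons to CAA. This shortens the uninterrupted run — and hence the
predicted onset — without changing the encoded polyglutamine tract, and
without cutting the DNA. `cagedit` implements the quantitative scaffolding
for this strategy:

| module | purpose |
| --- | --- |
| `repeat_model` | repeat-allele algebra: structure classes, uninterrupted-CAG / glutamine lengths, in-silico conversion, effective-CAG offsets |
| `guide_design` | protospacer register enumeration on the periodic repeat, PAM ranking, editor activity-window → CAG-site mapping |
| `amplicon_qc` | four-filter QC for paired amplicon reads (quality, mate concordance, CAG count, primer match) |
| `conversion_calling` | per-site conversion %, conversion-type spectrum, duplicated-interruption fraction, indels, allele-specific comparison |
| `onset_model` | exponential onset curve, residual-SS grid search for class-specific CAG offsets, predicted onset delay |
| `instability` | expansion index from fragment-analysis peak traces, OLS treatment regression |
| `synthetic_data` | seeded simulators for reads, onset cohorts and peak traces, with truth tables |

## Worked example

Convert the 42nd CAG of a canonical 43-CAG allele. The product is a
duplicated-interruption allele: two fewer uninterrupted CAG, the same 45
glutamines. With the fitted DI offset (−1) it behaves like a canonical
40-CAG allele, and with mean onsets of 48 y (43 CAG) and 60 y (40 CAG) the
predicted onset delay is 12 years:

```python
from cagedit.repeat_model import (
    RepeatStructureClass, apply_conversion, canonical_allele,
    glutamine_length, uninterrupted_cag_length, effective_cag,
)
from cagedit.onset_model import OnsetModel, onset_delay

a43 = canonical_allele(43)
edited = apply_conversion(a43, 42)
print("structure:        ", edited.structure.name)
print("uninterrupted CAG:", uninterrupted_cag_length(edited.codons))
print("glutamines:       ", glutamine_length(edited.codons))
offsets = {RepeatStructureClass.DI: -1}
print("effective CAG:    ", effective_cag(edited, offsets))
model = OnsetModel.from_table({43: 48.0, 40: 60.0})
print("predicted delay:  ", onset_delay(a43, 42, offsets, model), "years")
```

Output:

```text
structure:         DI
uninterrupted CAG: 41
glutamines:        45
effective CAG:     40
predicted delay:   12.0 years
```

Quantify editing outcomes from (here: simulated) paired amplicon reads:

```python
from cagedit.synthetic_data import ReadSimConfig, simulate_read_pairs
from cagedit.repeat_model import default_htt_template
from cagedit.amplicon_qc import QcParams, qc_filter
from cagedit.conversion_calling import (
    call_reads, per_site_conversion, duplicated_interruption_fractions,
)

template = default_htt_template((17,))
allele = template.allele_by_name("canonical_17")
config = ReadSimConfig(
    template=template,
    allele_mix={"canonical_17": 1.0},
    per_site_caa={"canonical_17": {2: 0.25, 16: 0.05}},
    indel_rate=0.0,
    n_pairs=2000,
    seed=7,
)
pairs, truth = simulate_read_pairs(config)
params = QcParams(primer_fwd=template.primer_fwd, primer_rev=template.primer_rev)
merged, report = qc_filter(pairs, params)
print("QC kept:", report.n_kept, "of", report.n_input)
calls = call_reads(merged, template)
pct = per_site_conversion(calls, allele)
print("site 2 conversion: %.2f%%" % pct[1])
di, _ = duplicated_interruption_fractions(calls)
print("DI read fraction:  %.2f%%" % di)
```

Output:

```text
QC kept: 2000 of 2000
site 2 conversion: 25.20%
DI read fraction:  4.50%
```

The same operations are exposed on the command line:

```console
$ cagedit predict-edits --spacer CTGCTGCTGCTGCTGCTGGA
strand	start	mismatches	pam	pam_rank	cag_sites
antisense	87	0	AGG	1	4,5
```

Run `cagedit --help` for the full command list (`qc`, `call-conversions`,
`predict-edits`, `estimate-offset`, `expansion-index`,
`instability-regress`, and the three `simulate-*` generators).

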