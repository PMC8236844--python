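# Deleterious/benign call conventions for the 12 dbNSFP missense predictors,
# the two meta-predictors and the splice-capable tools. Categorical tools list
# the annotation letters counted as deleterious resp. benign; numeric tools
# give an inclusive cutoff (value >= cutoff is deleterious unless
# direction: le). "." or an unparseable cell is always "missing".
tools:
  SIFT:
    kind: categorical
    deleterious: [D]
    benign: [T]
  Polyphen2_HDIV:
    kind: categorical
    deleterious: [D, P]
    benign: [B]
  Polyphen2_HVAR:
    kind: categorical
    deleterious: [D, P]
    benign: [B]
  LRT:
    kind: categorical
    deleterious: [D]
    benign: [N, U]
  MutationTaster:
    kind: categorical
    deleterious: [A, D]
    benign: [N, P]
  MutationAssessor:
    kind: categorical
    deleterious: [H, M]
    benign: [L, N]
  FATHMM:
    kind: categorical
    deleterious: [D]
    benign: [T]
  PROVEAN:
    kind: categorical
    deleterious: [D]
    benign: [N]
  MetaSVM:
    kind: categorical
    deleterious: [D]
    benign: [T]
  MetaLR:
    kind: categorical
    deleterious: [D]
    benign: [T]
  M-CAP:
    kind: categorical
    deleterious: [D]
    benign: [T]
  CADD:
    kind: numeric        # phred-scaled; >= 20 is the conventional deleterious cutoff
    cutoff: 20.0
meta:
  REVEL:
    cutoff: 0.5          # inclusive; Pathogenic vs Benign
  BayesDel:
    cutoff: -0.057       # inclusive; Damaging vs Tolerated
splice:
  HSF:
    kind: categorical    # imported Human Splicing Finder verdicts, never queried
    deleterious: [affected, broken, altered]
    benign: [no_impact, neutral]
  MutationTaster:        # carries the NNSplice splice-site evaluation
    kind: categorical
    deleterious: [A, D]
    benign: [N, P]
  CADD:
    kind: numeric
    cutoff: 20.0
  BayesDel:
    kind: numeric
    cutoff: -0.057
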