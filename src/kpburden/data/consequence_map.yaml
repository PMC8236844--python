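# Consequence vocabulary of the annotation dialect (ANNOVAR refGene strings)
# mapped onto the internal consequence classes. Unknown strings fall back to
# "other"; matching is case-insensitive after stripping whitespace.
missense:
  - nonsynonymous SNV
  - missense
stopgain:
  - stopgain
  - stopgain SNV
  - stop gain
stoploss:
  - stoploss
  - stoploss SNV
  - stop loss
frameshift_indel:
  - frameshift insertion
  - frameshift deletion
  - frameshift substitution
  - frameshift
inframe_indel:
  - nonframeshift insertion
  - nonframeshift deletion
  - nonframeshift substitution
  - inframe_indel
splicing:
  - splicing
  - splice
  - exonic;splicing
synonymous:
  - synonymous SNV
  - synonymous
utr5:
  - UTR5
  - 5'UTR
utr3:
  - UTR3
  - 3'UTR
intronic:
  - intronic
intergenic:
  - intergenic
other:
  - upstream
  - downstream
  - ncRNA_exonic
  - ncRNA_intronic
  - unknown
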