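# Literature-default N2O pathway endmembers -- EDITABLE configuration data.
#
# Values are indicative means/sds (permil) compiled from published pure-culture
# and field constraints on marine N2O formation pathways; replace them with
# study-specific values when available.
#
# Sign convention for `reduction` (the Rayleigh term): the forward model adds
# mu * ln(r) to each signal, with r the residual unreduced N2O fraction.
# ln(r) < 0 for r < 1, so mu must be NEGATIVE for reduction to ENRICH the
# residual pool (the usual case for N2O consumption).
pathways:
  aN:            # archaeal nitrification
    d15n_bulk: {mean: 0.0, sd: 2.0}
    d18o:      {mean: 42.0, sd: 2.0}
    sp:        {mean: 30.0, sd: 1.5}
  bN:            # bacterial nitrification (NH2OH pathway)
    d15n_bulk: {mean: -25.0, sd: 2.5}
    d18o:      {mean: 30.0, sd: 2.0}
    sp:        {mean: 33.0, sd: 2.0}
  nD:            # nitrifier denitrification
    d15n_bulk: {mean: -35.0, sd: 2.5}
    d18o:      {mean: 18.0, sd: 2.0}
    sp:        {mean: -2.0, sd: 1.5}
  bD:            # (heterotrophic) denitrification
    d15n_bulk: {mean: -15.0, sd: 2.5}
    d18o:      {mean: 25.0, sd: 2.0}
    sp:        {mean: -4.0, sd: 1.5}
reduction:
  d15n_bulk: {mean: -7.0, sd: 1.0}
  d18o:      {mean: -15.0, sd: 1.5}
  sp:        {mean: -5.0, sd: 1.0}
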