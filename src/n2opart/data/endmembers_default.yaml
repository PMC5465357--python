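# Default endmember table for the four-process N2O mass balance.
#
# NON-AUTHORITATIVE: these are literature-guided placeholder values, not a
# calibrated endmember set.  Any serious application should supply its own
# table via --endmembers.
#
# dd15N is on the nitrate-referenced scale (d15N_NO3 - d15N_N2O expected if
# the process acted alone), permil.  Denitrification dd15N endmembers are
# low because diffusion limitation suppresses expression of the intrinsic
# enzyme-level isotope effects in organic-rich sediments.  SP in permil
# (fDNF ~37 from the fungal P450nor pathway; cDNF >10 and up to ~26 for
# Fe(II)-driven nitrite reduction; AMO ~33; bDNF/nDNF low/negative).
# o_transfer is the coefficient multiplying the steady-state NO2- 17O-excess
# in the oxygen balance: 1 for NO2--consuming denitrification, 0 for AMO
# (O from O2/H2O) and for nDNF in the base case (its NO2- derives directly
# from NH4+ oxidation and carries no anomaly).
#
# AMO dd15N is null because it is derived per record from measured d15N of
# NO3- and TRN plus amo_eps (the NH3->N2O fractionation, product depleted).
# sp_eps_red is the kinetic isotope effect on SP of N2O reduction: -6 permil
# (reduction raises the SP of the residual N2O pool).

case: fDNF
sp_eps_red: -6.0
n15_eps_red: 0.0
amo_eps: {mean: 3.7, sd: 3.0}
endmembers:
  bDNF: {dd15N: 0.0,  dd15N_sd: 2.0, SP: -5.0, SP_sd: 5.0, o_transfer: 1.0}
  fDNF: {dd15N: 0.0,  dd15N_sd: 2.0, SP: 37.0, SP_sd: 3.0, o_transfer: 1.0}
  cDNF: {dd15N: 0.0,  dd15N_sd: 2.0, SP: 16.0, SP_sd: 5.0, o_transfer: 1.0}
  AMO:  {dd15N: null, dd15N_sd: 3.0, SP: 33.0, SP_sd: 4.0, o_transfer: 0.0}
  nDNF: {dd15N: 56.9, dd15N_sd: 5.0, SP: -5.0, SP_sd: 5.0, o_transfer: 0.0}
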