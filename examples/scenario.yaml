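# Reference scenario: ambient-O2 biochemistry with an evenly split
# mesophyll resistance and a mixed organelle arrangement.
photo:
  Vcmax: 80      # umol m-2 s-1
  J: 125         # umol m-2 s-1
  Rd: 1          # umol m-2 s-1
  KmC: 291       # ubar
  KmO: 194       # mbar
  Sco: 3.1       # mbar/ubar  (O defaults to ambient 210 mbar)
resistance:
  gm_dif: 0.4    # mol m-2 s-1 bar-1
  omega: 0.5
  sigma: 0.5     # or give lam (and optionally k) instead
ci_start: 50     # ubar
ci_stop: 400
ci_step: 27
o2_levels: [20, 210, 400]   # mbar, for generate/fit
noise_sd: 0.2    # umol m-2 s-1, on A only
seed: 42
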