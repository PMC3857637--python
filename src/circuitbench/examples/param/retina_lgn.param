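{
'component': 'circuitbench.retina.RetinaLGN',
'params': {
    'sigma_c': 0.2,       # deg, DoG centre
    'sigma_s': 0.6,       # deg, DoG surround
    'A_c': 1.0,
    'A_s': 1.0,
    'tau_lgn': 10.0,      # ms, temporal low-pass
    'baseline_rate': 10.0,   # spikes/s
    'gain': 100.0,           # spikes/s per unit drive
    'max_rate': 200.0,       # spikes/s
    'density': 20.0,         # cells/deg^2 per polarity
    'recorders': url("lgn_rec") }
}
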