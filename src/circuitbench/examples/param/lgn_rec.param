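{
"Spikes" : {
    'component': 'circuitbench.sheets.population_selector.RCRandomN',
    'variables': ("spikes",),
    'params':  {'num_of_cells': 100} }
}
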