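{
'component': 'circuitbench.sheets.CorticalUniformSheet',
'params': {
    'name': 'V1_Inh_L4',
    'sx': 5000.0,
    'sy': 5000.0,
    'density': 16.0,
    'magnification_factor': 5000.0,
    'cell': {
        'model': 'IF_cond_exp',
        'params': {
            'v_thresh': -57.0,
            'v_rest': -70.0,
            'v_reset': -70.0,
            'cm': 0.29,
            'tau_m': 10.0,
            'tau_refrac': 1.0,
            'tau_syn_E': 1.5,
            'tau_syn_I': 10.0,
            'e_rev_E': 0.0,
            'e_rev_I': -75.0,
            'i_offset': 0.0 },
        'initial_values': {
            'v': PyNNDistribution(name='uniform', params=(-60, -50))}},
    'background_noise': {
        'exc_firing_rate': 2000.0,
        'exc_weight': 0.00145,
        'inh_firing_rate': 2000.0,
        'inh_weight': 0.00030 },
    'recorders': url("l4_inh_rec") },
'L4InhL4ExcConnection': {
    'target_synapses': 'inhibitory',
    'short_term_plasticity': {},
    'weight_functions': {
        'f1': {
            'component': 'circuitbench.connectors.V1PushPullArborization',
            'params': {
                'or_sigma': 0.26,
                'phase_sigma': 0.52,
                'target_synapses': 'inhibitory' }},
        'f2': {
            'component': 'circuitbench.connectors.HyperbolicConnectorFunction',
            'params': {
                'theta': 207.76,
                'alpha': 0.013944 }}},
    'delay_functions': {},
    'weight_expression': 'f1*f2',
    'delay_expression': '2',
    'base_weight': ref('l4_cortex_exc.L4ExcL4ExcConnection.base_weight')*1.5,
    'num_samples': 72 },
'L4InhL4InhConnection': ref('l4_cortex_inh.L4InhL4ExcConnection'),
'AfferentConnection': {
    'aspect_ratio': UniformDist(min=0.57, max=0.57),
    'size': UniformDist(min=0.46, max=0.46),
    'orientation_preference': UniformDist(min=0.0, max=3.141592653589793),
    'phase': UniformDist(min=0.0, max=6.283185307179586),
    'frequency': UniformDist(min=0.8, max=0.8),
    'or_map_location': './or_map',
    'specific_arborization': {
        'weight_factor': ref('l4_cortex_exc.L4ExcL4ExcConnection.base_weight')*2,
        'num_samples': 94,
        'target_synapses': 'excitatory',
        'short_term_plasticity': {
            'u': 0.75,
            'tau_rec': 125.0,
            'tau_psc': 1.5,
            'tau_fac': 0.0 }}}
}
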