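cytochrome	substrate	relation	perpetrator	substrate_ucds	perpetrator_ucds
CYP1A2	FLECAINID	p_inhib	NORFLOXACIN	3400890352246 or 3400892468143 or 3400892468204 or 3400892468372 or 3400892468433 or 3400892498478 or 3400892635408 or 3400893089811 or 3400893096093 or 3400893104170 or 3400893114117 or 3400893123560 or 3400894250951	3400891057980 or 3400892475356 or 3400892482859 or 3400892555980 or 3400892556062 or 3400892556123 or 3400892558363 or 3400892563336 or 3400892571140 or 3400892686783 or 3400892701325 or 3400892884516
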