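# activity / stability vocabulary for Temperature and pH sentence classification
activity
activities
active
stability
stable
thermostable
thermostability
retained
retains
retaining
residual
incubated
incubation
denatured
inactivated
inactivation
half-life
exhibited
displayed
optimum
optimal
maximum
maximal
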