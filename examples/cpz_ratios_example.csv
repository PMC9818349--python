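drug,multiplier,source
chlorpromazine,1.0,illustrative-example-not-clinical
haloperidol,50.0,illustrative-example-not-clinical
risperidone,100.0,illustrative-example-not-clinical
olanzapine,30.0,illustrative-example-not-clinical
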