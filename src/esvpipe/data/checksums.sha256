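29e105a2966cf08920fadaa55fd3e045eeae7550b27f5f72eb6245c37f28561b  cnlucc_reclass.csv
8b035973c4e1cdacd4a5cd1a000aecbe4bfb9335d400b17f4a5589c778146352  disturbance_coefficients.csv
7c92bafb21a1b21a8e55fc3f9024a032196fefee7d151488c6364d654fe95d14  esv_by_class_function.csv
526253f574e08643739b24feb5410e80a3cf358a758405c6b13952ada7a46dde  esv_coefficients.csv
a6447cfbf2d533dbf3a0afd9bccd7c87d36094a75442d7d0b4c1f297cbc34a1e  implied_areas.csv
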