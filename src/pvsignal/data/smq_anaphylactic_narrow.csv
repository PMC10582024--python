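smq_name,scope,pt_term
anaphylactic reaction,narrow,anaphylactic reaction
anaphylactic reaction,narrow,anaphylactic shock
anaphylactic reaction,narrow,anaphylactic transfusion reaction
anaphylactic reaction,narrow,anaphylactoid reaction
anaphylactic reaction,narrow,circulatory collapse
anaphylactic reaction,narrow,kounis syndrome
anaphylactic reaction,narrow,procedural shock
anaphylactic reaction,narrow,shock
anaphylactic reaction,narrow,shock syndrome
anaphylactic reaction,narrow,type 1 hypersensitivity
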