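pdb_id,mutations,ddG_pH5.35,stability_class
3c80,R96Y,-4.7,unstable
3fi5,R96W,-4.5,unstable
3c7z,D89A;R96H,-3.8,unstable
3c82,K85A;R96H,-3.6,unstable
3c8q,R96D,-3.5,unstable
3cdt,R96N,-3.0,unstable
3cdv,R96M,-2.7,unstable
3c8r,R96G,-2.6,unstable
3cdq,R96S,-2.6,stable
3c8s,R96E,-2.5,stable
3cdo,R96V,-2.4,stable
3c7y,R96A,-2.0,stable
3c81,K85A,-0.6,stable
3c83,D89A,-0.5,stable
3cdr,R96Q,-0.3,stable
3c7w,R96K,0.0,stable
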