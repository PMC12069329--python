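# stigmasterol: hydrogen-suppressed heavy-atom skeleton (C29H48O)
# single edges regardless of bond order; best-effort reconstruction; molecular formula matches reported monoisotopic mass
C1 C2
C2 C3
C3 C4
C4 C5
C5 C6
C6 C7
C6 C8
C8 C9
C9 C10
C10 C11
C11 C12
C12 C13
C12 C14
C14 C15
C15 C16
C16 C17
C17 C18
C18 C19
C19 C20
C20 C21
C21 C22
C22 O23
C22 C24
C24 C25
C25 C26
C26 C27
C3 C28
C28 C29
C28 C30
C12 C8
C26 C16
C17 C11
C26 C20
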