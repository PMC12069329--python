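# tirucallol: hydrogen-suppressed heavy-atom skeleton (C30H50O)
# single edges regardless of bond order; best-effort reconstruction; molecular formula matches reported monoisotopic mass
C1 C2
C2 C3
C3 C4
C4 C5
C5 C6
C6 C7
C6 C8
C2 C9
C9 C10
C10 C11
C11 C12
C12 C13
C12 C14
C14 C15
C14 C16
C16 C17
C17 C18
C18 C19
C19 C20
C20 C21
C21 C22
C22 C23
C23 C24
C23 C25
C23 C26
C26 O27
C26 C28
C28 C29
C29 C30
C30 C31
C14 C9
C30 C18
C19 C12
C30 C22
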