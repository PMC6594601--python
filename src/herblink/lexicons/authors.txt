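# Botanical/classical authors cited inside plant names, with inflected
# forms. Format: canonical label ":" comma-separated surface forms
# (matched against normalized tokens, so u/v i/j y/i unification applies).
Theophrastus: theophrastus, theophrasti
Pliny: plinius, plinii
Fuchs: fuchs, fuchsii
Dioscorides: dioscorides, dioscoridis
Ruel: ruellius, ruellii, ruel
Virgil: uirgilius, uirgilii
Paulus Aegineta: aegineta, aeginetae
Mattioli: matthiolus, matthioli, mattioli
Anguillara: anguillara, anguillarae
Tragus: tragus, tragi
Cordus: cordus, cordi
Galen: galenus, galeni
Clusius: clusius, clusii
Gesner: gesnerus, gesneri
Apuleius: apuleius, apuleii
Oribasius: oribasius, oribasii
Guilandinus: guilandinus, guilandini
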