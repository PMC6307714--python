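"""Exception hierarchy."""


class CgfoldError(Exception):
    """Base class for package errors."""


class MissingAtomError(CgfoldError):
    def __init__(self, residue: int, atom: str):
        self.residue = residue
        self.atom = atom
        super().__init__(f"residue {residue}: missing backbone atom {atom}")


class ChainBreakError(CgfoldError):
    def __init__(self, residue: int, distance: float):
        self.residue = residue
        self.distance = distance
        super().__init__(
            f"chain break between residues {residue} and {residue + 1}: "
            f"C-N distance {distance:.2f} A > 2.0 A"
        )


class GeometryError(CgfoldError):
    pass


class DegenerateGeometryError(GeometryError):
    pass


class IntegrationError(CgfoldError):
    def __init__(self, atom_index: int):
        self.atom_index = atom_index
        super().__init__(f"non-finite force on atom {atom_index}")


class ParameterMismatchError(CgfoldError):
    pass


class ShapeError(CgfoldError):
    pass


class SchemaError(CgfoldError):
    pass


class UnsupportedVersionError(SchemaError):
    pass


class ConfigError(CgfoldError):
    pass
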